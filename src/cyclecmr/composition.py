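"""Sex/age composition from SECR densities, with capture-history bootstrap SEs.

Class proportions are ratios of SECR densities within a session.  Their
uncertainty is estimated by resampling whole individual capture histories
with replacement (histories are never altered, sample size is preserved),
refitting the SECR models on each resample, and taking the standard
deviation of the class proportions across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CLASSES, SessionHistory, TrapGrid
from .secr import HabitatMask, estimate_session

__all__ = ["ProportionEstimate", "proportions_from_densities", "bootstrap_proportions"]

DEFAULT_N_BOOT = 200


@dataclass
class ProportionEstimate:
    sexage: str
    proportion: float
    se: float
    grid_id: str
    year: int
    primary: int
    n_boot: int = 0
    n_converged: int = 0
    flags: list = field(default_factory=list)


def proportions_from_densities(density_table: pd.DataFrame) -> pd.DataFrame:
    """Class proportions D_c / sum(D) per (year, primary, grid) session.

    Sessions whose densities are all zero (or unusable) are flagged with NaN
    proportions rather than dropped.
    """
    rows = []
    for (year, primary, gid), sub in density_table.groupby(["year", "primary", "grid_id"]):
        d = sub.set_index("sexage")["density_ha"].reindex(CLASSES)
        total = np.nansum(d.values)
        for cls in CLASSES:
            dc = d.get(cls, np.nan)
            if total > 0 and np.isfinite(dc):
                p, flag = dc / total, ""
            else:
                p, flag = np.nan, "undefined_proportion"
            rows.append(dict(year=year, primary=primary, grid_id=gid, sexage=cls,
                             proportion=p, total_density_ha=total, flags=flag))
    return pd.DataFrame(rows)


def _resample_histories(histories: list[SessionHistory], rng) -> list[SessionHistory]:
    """Resample whole histories with replacement, keeping the sample size.

    Duplicated individuals get fresh synthetic ids so the refit treats them
    as distinct animals; detection matrices are shared read-only.
    """
    n = len(histories)
    idx = rng.integers(0, n, size=n)
    out = []
    for j, i in enumerate(idx):
        h = histories[i]
        out.append(SessionHistory(
            individual_id=f"{h.individual_id}~b{j}", year=h.year, primary=h.primary,
            grid_id=h.grid_id, detections=h.detections, sex=h.sex,
            age_class=h.age_class))
    return out


def bootstrap_proportions(
    histories: list[SessionHistory],
    grid: TrapGrid,
    mask: HabitatMask,
    B: int = DEFAULT_N_BOOT,
    seed: int = 0,
    pooling_threshold: int = 5,
    sigma_starts_m=(15.0, 30.0, 60.0),
) -> list[ProportionEstimate]:
    """Bootstrap class proportions for one session (B refits, default 200).

    Each replicate resamples capture histories with replacement, reruns the
    SECR estimation (with the same high/low-abundance routing as the point
    estimate) and recomputes proportions; the estimate is the replicate mean
    and the SE the replicate standard deviation.  Non-convergent replicates
    are dropped and counted.
    """
    if not histories:
        raise ValueError("empty session")
    year, primary, gid = histories[0].year, histories[0].primary, histories[0].grid_id
    rng = np.random.default_rng(seed)
    props = np.full((B, len(CLASSES)), np.nan)
    n_ok = 0
    for b in range(B):
        rep = _resample_histories(histories, rng)
        try:
            ests = estimate_session(rep, grid, mask, pooling_threshold=pooling_threshold,
                                    sigma_starts_m=sigma_starts_m)
        except Exception:
            continue
        d = {e.sexage: e.density for e in ests}
        total = sum(v for v in d.values() if np.isfinite(v))
        if not np.isfinite(total) or total <= 0:
            continue
        props[b] = [d.get(c, 0.0) / total for c in CLASSES]
        n_ok += 1
    out = []
    for j, cls in enumerate(CLASSES):
        col = props[:, j]
        col = col[np.isfinite(col)]
        flags = []
        if len(col) >= 2:
            mean, se = float(col.mean()), float(col.std(ddof=1))
        elif len(col) == 1:
            mean, se = float(col[0]), np.nan
            flags.append("se_undefined")
        else:
            mean, se = np.nan, np.nan
            flags.append("all_replicates_failed")
        out.append(ProportionEstimate(
            sexage=cls, proportion=mean, se=se, grid_id=gid, year=year,
            primary=primary, n_boot=B, n_converged=n_ok, flags=flags))
    return out


def proportions_table(estimates: list[ProportionEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(year=e.year, primary=e.primary, grid_id=e.grid_id, sexage=e.sexage,
             proportion=e.proportion, se=e.se, n_boot=e.n_boot,
             n_converged=e.n_converged, flags=";".join(e.flags))
        for e in estimates
    ])
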