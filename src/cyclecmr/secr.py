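"""Spatially explicit capture-recapture with half-normal detection.

Detection probability of an animal whose activity centre is at distance *d*
from a trap is g(d) = g0 * exp(-d^2 / (2 sigma^2)).  Traps are single-capture
live traps; we use the standard multi-catch (competing-hazard) likelihood in
which per-occasion trap hazards h_k = -log(1 - g(d_k)) compete, so an animal
at x is caught somewhere with probability 1 - exp(-H(x)), H = sum_k h_k, and
ends up in trap k with probability (h_k/H)(1 - exp(-H)).

Densities come from the likelihood conditional on the number of animals
detected: detection parameters are maximised first, then each detected
individual contributes the reciprocal of its effective sampling area
a(theta) = integral over the habitat mask of the probability of being
detected at least once, giving the Horvitz-Thompson estimator
D-hat = sum_i 1/a_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._numutil import expit, logit, numeric_hessian, safe_vcov
from .datamodel import CLASSES, SessionHistory, TrapGrid, build_session_histories, sessions

__all__ = [
    "HabitatMask", "DetectionFit", "DensityEstimate", "halfnormal",
    "build_mask", "fit_conditional", "derive_density", "estimate_all_sessions",
]

DEFAULT_BUFFER_M = 100.0
DEFAULT_MASK_SPACING_M = 10.0
POOLING_THRESHOLD = 5  # <= this many distinct individuals in a session -> pooled fit
SIGMA_STARTS_M = (15.0, 30.0, 60.0)


def halfnormal(d, g0: float, sigma_m: float):
    """Half-normal detection function g0 * exp(-d^2 / (2 sigma^2))."""
    if sigma_m <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_m}")
    d = np.asarray(d, dtype=float)
    out = g0 * np.exp(-(d**2) / (2.0 * sigma_m**2))
    return float(out) if out.ndim == 0 else out


@dataclass
class HabitatMask:
    """Regular lattice of potential activity-centre locations around a grid."""

    points: np.ndarray  # (M, 2) metres
    spacing_m: float
    buffer_m: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def cell_area_ha(self) -> float:
        return self.spacing_m**2 / 1e4

    @property
    def area_ha(self) -> float:
        return self.n_points * self.cell_area_ha


def build_mask(grid: TrapGrid, buffer_m: float = DEFAULT_BUFFER_M,
               spacing_m: float = DEFAULT_MASK_SPACING_M) -> HabitatMask:
    """Lattice covering the station bounding box expanded by ``buffer_m``.

    The default 100-m buffer corresponds to three to four times the daily
    movement of the animals, beyond which detection is negligible.
    """
    if spacing_m <= 0:
        raise ValueError("mask spacing must be positive")
    xy = grid.station_xy()
    lo = xy.min(axis=0) - buffer_m
    hi = xy.max(axis=0) + buffer_m
    xs = np.arange(lo[0], hi[0] + spacing_m / 2, spacing_m)
    ys = np.arange(lo[1], hi[1] + spacing_m / 2, spacing_m)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return HabitatMask(points=pts, spacing_m=float(spacing_m), buffer_m=float(buffer_m))


@dataclass
class DetectionFit:
    g0: float
    sigma_m: float
    loglik: float
    esa_ha: float                      # effective sampling area a(theta-hat)
    n_individuals: int
    n_occasions: int
    vcov_link: np.ndarray              # vcov of (logit g0, log sigma)
    converged: bool = True
    flags: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)  # e.g. {"grid": ..., "class": ...}


@dataclass
class DensityEstimate:
    density: float       # animals / ha
    se: float
    lo95: float
    hi95: float
    n: int
    sexage: str = "all"
    grid_id: str = ""
    year: int = 0
    primary: int = 0
    pooled: bool = False
    converged: bool = True
    flags: list = field(default_factory=list)
    g0: float = np.nan
    sigma_m: float = np.nan


# ---------------------------------------------------------------------------
# Conditional likelihood

class _SessionData:
    """Pre-digested capture data of one session for fast likelihood evaluation."""

    def __init__(self, histories: list[SessionHistory], grid: TrapGrid, mask: HabitatMask):
        if not histories:
            raise ValueError("no detections: cannot fit a detection model")
        self.n = len(histories)
        self.n_occasions = histories[0].detections.shape[0]
        self.grid = grid
        self.mask = mask
        self.d2 = _trap_mask_d2(grid, mask)    # (K traps, M mask)
        # caught-trap index per (individual, occasion), sparse by events
        ind_idx, trap_idx = [], []
        for i, h in enumerate(histories):
            occ, trap = np.nonzero(h.detections)
            ind_idx.extend([i] * len(occ))
            trap_idx.extend(trap.tolist())
        self.ev_ind = np.asarray(ind_idx, dtype=int)
        self.ev_trap = np.asarray(trap_idx, dtype=int)
        self.caught_per_ind = np.bincount(self.ev_ind, minlength=self.n).astype(float)

    def negloglik(self, params: np.ndarray) -> float:
        g0 = float(expit(params[0]))
        sigma = float(np.exp(params[1]))
        g = g0 * np.exp(-self.d2 / (2.0 * sigma**2))
        g = np.clip(g, 1e-12, 1.0 - 1e-12)
        h = -np.log1p(-g)                      # (K, M) hazards
        H = h.sum(axis=0)                      # (M,)
        S = self.n_occasions
        log_p_miss = -H                        # per-occasion miss log-prob
        log_p_caught = np.log1p(-np.exp(-H))   # caught-somewhere log-prob
        # overall detection prob over the whole session
        log_pdot = np.log1p(-np.exp(-S * H))
        a_theta = self.mask.cell_area_ha * np.exp(logsumexp(log_pdot))
        c = self.caught_per_ind[:, None]       # (n, 1)
        m = S - c
        # per-individual, per-mask-point log Pr(history | x); the trap term
        # sum_s log h_{k_s}(x) accumulates event-wise (histories are sparse)
        logA = np.zeros((self.n, H.size))
        log_h_ev = np.log(h[self.ev_trap])     # (E, M)
        for row, i in enumerate(self.ev_ind):
            logA[i] += log_h_ev[row]
        logA += -c * np.log(H)[None, :] + c * log_p_caught[None, :] + m * log_p_miss[None, :]
        ll = logsumexp(logA, axis=1) + np.log(self.mask.cell_area_ha) - np.log(a_theta)
        return -float(ll.sum())

    def esa(self, params: np.ndarray) -> float:
        g0 = float(expit(params[0]))
        sigma = float(np.exp(params[1]))
        g = np.clip(g0 * np.exp(-self.d2 / (2.0 * sigma**2)), 1e-12, 1 - 1e-12)
        H = (-np.log1p(-g)).sum(axis=0)
        pdot = -np.expm1(-self.n_occasions * H)
        return float(self.mask.cell_area_ha * pdot.sum())


def fit_conditional(
    histories: list[SessionHistory],
    grid: TrapGrid,
    mask: HabitatMask,
    share_detection_across_groups: bool = True,
    g0_start: float = 0.2,
    sigma_starts_m=SIGMA_STARTS_M,
    labels: dict | None = None,
) -> DetectionFit:
    """Maximise the conditional-on-capture multi-catch likelihood over (g0, sigma).

    Optimisation runs on (logit g0, log sigma) by Nelder-Mead from each start
    in ``sigma_starts_m``; the best likelihood wins, ties broken by smallest
    sigma.  Variance is from the numeric Hessian at the optimum.  A session in
    which no animal is ever recaptured at a second trap leaves sigma (and
    hence g0) weakly identified; such fits are flagged non-identifiable.
    """
    data = _SessionData(histories, grid, mask)
    flags = []
    moved = any(h.n_captures > 1 for h in histories)
    if not moved:
        flags.append("non_identifiable")
    # deterministic starts over sigma; prescreen by likelihood, optimise from
    # the best, fall back to the others on failure; ties go to smallest sigma
    starts = [np.array([logit(g0_start), np.log(s0)]) for s0 in sigma_starts_m]
    order = np.argsort([data.negloglik(x0) for x0 in starts], kind="stable")
    bounds = [(-10.0, 10.0), (np.log(2.0), np.log(1000.0))]
    best = None
    for j in order:
        res = minimize(data.negloglik, starts[j], method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 200})
        cand = (res.fun, np.exp(res.x[1]), res)
        if best is None or cand[0] < best[0] - 1e-9 or (
                abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]):
            best = cand
        if res.success:
            break
    res = best[2]
    params = res.x
    converged = bool(res.success) and "non_identifiable" not in flags
    if not res.success:
        flags.append("optimizer_not_converged")
    H = numeric_hessian(data.negloglik, params)
    vcov = safe_vcov(H)
    return DetectionFit(
        g0=float(expit(params[0])),
        sigma_m=float(np.exp(params[1])),
        loglik=-float(res.fun),
        esa_ha=data.esa(params),
        n_individuals=data.n,
        n_occasions=data.n_occasions,
        vcov_link=vcov,
        converged=converged,
        flags=flags,
        labels=labels or {},
    )


def derive_density(fit: DetectionFit, n_detected: int, mask: HabitatMask,
                   grid: TrapGrid | None = None, **meta) -> DensityEstimate:
    """Horvitz-Thompson density from a conditional fit: D = n / a(theta).

    SE combines the delta-method contribution of detection-parameter
    uncertainty with a Poisson term for the count; the 95% CI is lognormal,
    which keeps the lower bound positive.
    """
    if n_detected == 0:
        return DensityEstimate(density=0.0, se=np.nan, lo95=np.nan, hi95=np.nan,
                               n=0, flags=["no_detections"], converged=fit.converged,
                               g0=fit.g0, sigma_m=fit.sigma_m, **meta)
    if fit.esa_ha <= 0:
        raise ValueError("effective sampling area is zero")
    # rebuild esa as a function of link parameters for the delta method
    if grid is None:
        a_of = None
    else:
        d2 = _trap_mask_d2(grid, mask)

        def a_of(params):
            g0 = float(expit(params[0]))
            sigma = float(np.exp(params[1]))
            g = np.clip(g0 * np.exp(-d2 / (2.0 * sigma**2)), 1e-12, 1 - 1e-12)
            H = (-np.log1p(-g)).sum(axis=0)
            pdot = -np.expm1(-fit.n_occasions * H)
            return float(mask.cell_area_ha * pdot.sum())

    a = fit.esa_ha
    D = n_detected / a
    var_n = n_detected / a**2  # Poisson count variation
    if a_of is not None and np.all(np.isfinite(fit.vcov_link)):
        params = np.array([logit(fit.g0), np.log(fit.sigma_m)])
        grad = np.empty(2)
        for i in range(2):
            step = 1e-4 * max(1.0, abs(params[i]))
            xp, xm = params.copy(), params.copy()
            xp[i] += step
            xm[i] -= step
            grad[i] = -n_detected * (a_of(xp) - a_of(xm)) / (2 * step) / a**2
        var_theta = float(grad @ fit.vcov_link @ grad)
        var_theta = max(var_theta, 0.0)
    else:
        var_theta = 0.0
    se = float(np.sqrt(var_n + var_theta))
    cv2 = (se / D) ** 2
    w = np.exp(1.96 * np.sqrt(np.log(1 + cv2)))
    return DensityEstimate(density=float(D), se=se, lo95=float(D / w), hi95=float(D * w),
                           n=n_detected, converged=fit.converged,
                           flags=list(fit.flags), g0=fit.g0, sigma_m=fit.sigma_m, **meta)


_D2_CACHE: dict = {}


def _trap_mask_d2(grid: TrapGrid, mask: HabitatMask) -> np.ndarray:
    key = (grid.grid_id, grid.n_cols, grid.n_rows, grid.spacing_m,
           mask.spacing_m, mask.buffer_m, mask.n_points,
           float(mask.points[0, 0]), float(mask.points[-1, 1]))
    d2 = _D2_CACHE.get(key)
    if d2 is None:
        trap_xy = grid.station_xy()
        diff = trap_xy[:, None, :] - mask.points[None, :, :]
        d2 = np.einsum("kmi,kmi->km", diff, diff)
        if len(_D2_CACHE) > 16:
            _D2_CACHE.clear()
        _D2_CACHE[key] = d2
    return d2


# ---------------------------------------------------------------------------
# Batch estimation with high/low-abundance routing

def estimate_session(
    histories: list[SessionHistory],
    grid: TrapGrid,
    mask: HabitatMask,
    pooling_threshold: int = POOLING_THRESHOLD,
    min_class_n: int = 3,
    sigma_starts_m=SIGMA_STARTS_M,
) -> list[DensityEstimate]:
    """Density per sex-age class for one session.

    Low-abundance sessions (<= ``pooling_threshold`` distinct individuals)
    get one pooled detection fit with class-wise Horvitz-Thompson counts;
    larger sessions get separate fits per class.  Classes too sparse to fit
    on their own (< ``min_class_n``) borrow the pooled detection fit and are
    flagged.
    """
    year, primary, gid = histories[0].year, histories[0].primary, histories[0].grid_id
    meta = dict(grid_id=gid, year=year, primary=primary)
    n_ind = len(histories)
    by_class: dict[str, list[SessionHistory]] = {c: [] for c in CLASSES}
    for h in histories:
        if h.age_class in ("adult", "juvenile"):
            by_class[h.sexage].append(h)
    out: list[DensityEstimate] = []
    pooled = n_ind <= pooling_threshold
    pooled_fit = None
    if pooled or any(0 < len(v) < min_class_n for v in by_class.values()):
        pooled_fit = fit_conditional(histories, grid, mask,
                                     share_detection_across_groups=True,
                                     sigma_starts_m=sigma_starts_m,
                                     labels={"grid": gid, "class": "all"})
    for cls in CLASSES:
        hs = by_class[cls]
        if pooled or (hs and len(hs) < min_class_n):
            est = derive_density(pooled_fit, len(hs), mask, grid=grid,
                                 sexage=cls, pooled=True, **meta)
            if not pooled:
                est.flags.append("sparse_class_pooled_detection")
        elif not hs:
            est = DensityEstimate(density=0.0, se=np.nan, lo95=np.nan, hi95=np.nan,
                                  n=0, sexage=cls, pooled=pooled,
                                  flags=["no_detections"], **meta)
        else:
            try:
                fit = fit_conditional(hs, grid, mask, share_detection_across_groups=False,
                                      sigma_starts_m=sigma_starts_m,
                                      labels={"grid": gid, "class": cls})
                if "non_identifiable" in fit.flags:
                    # no within-class recaptures: borrow the pooled detection fit
                    if pooled_fit is None:
                        pooled_fit = fit_conditional(
                            histories, grid, mask, share_detection_across_groups=True,
                            sigma_starts_m=sigma_starts_m,
                            labels={"grid": gid, "class": "all"})
                    fit = pooled_fit
                    est = derive_density(fit, len(hs), mask, grid=grid,
                                         sexage=cls, pooled=True, **meta)
                    est.flags.append("class_detection_from_pooled")
                else:
                    est = derive_density(fit, len(hs), mask, grid=grid,
                                         sexage=cls, pooled=False, **meta)
            except Exception as exc:  # keep the batch alive, flag the row
                est = DensityEstimate(density=np.nan, se=np.nan, lo95=np.nan,
                                      hi95=np.nan, n=len(hs), sexage=cls,
                                      converged=False, flags=[f"fit_failed:{exc}"], **meta)
        out.append(est)
    return out


def esa_from_params(grid: TrapGrid, mask: HabitatMask, g0: float, sigma_m: float,
                    n_occasions: int) -> float:
    """Effective sampling area (ha) for given detection parameters."""
    d2 = _trap_mask_d2(grid, mask)
    g = np.clip(g0 * np.exp(-d2 / (2.0 * sigma_m**2)), 1e-12, 1 - 1e-12)
    H = (-np.log1p(-g)).sum(axis=0)
    pdot = -np.expm1(-n_occasions * H)
    return float(mask.cell_area_ha * pdot.sum())


def estimate_all_sessions(events, grids, buffer_m: float = DEFAULT_BUFFER_M,
                          mask_spacing_m: float = DEFAULT_MASK_SPACING_M,
                          pooling_threshold: int = POOLING_THRESHOLD,
                          n_occasions: int | None = None,
                          sigma_starts_m=SIGMA_STARTS_M):
    """Density table over every (year, primary, grid) session in the dataset.

    Returns a pandas DataFrame with one row per class x session.  Per-session
    failures become flagged rows; the batch never aborts.  Sessions without
    any within-session recapture cannot identify (g0, sigma) on their own --
    the conditional likelihood then degenerates toward a vanishing sampling
    area -- so a second pass recomputes their densities using the median
    detection parameters of the identifiable sessions on the same grid
    (falling back to the study-wide median), flagged
    ``detection_from_reference``.
    """
    import pandas as pd

    gmap = {g.grid_id: g for g in grids}
    masks = {g.grid_id: build_mask(g, buffer_m, mask_spacing_m) for g in grids}
    rows: list[DensityEstimate] = []
    occ_by_session: dict = {}
    for (year, primary, gid), evs in sorted(sessions(events).items()):
        grid = gmap[gid]
        hs = build_session_histories(evs, grid, n_occasions=n_occasions)
        occ_by_session[(year, primary, gid)] = hs[0].detections.shape[0] if hs else 0
        ests = estimate_session(hs, grid, masks[gid],
                                pooling_threshold=pooling_threshold,
                                sigma_starts_m=sigma_starts_m)
        rows.extend(ests)
    # second pass: reference detection for non-identifiable sessions
    ok = [e for e in rows if np.isfinite(e.g0) and "non_identifiable" not in e.flags
          and "fit_failed" not in ";".join(map(str, e.flags))]
    ref_all = (float(np.median([e.g0 for e in ok])), float(np.median([e.sigma_m for e in ok]))) if ok else (0.2, 15.0)
    ref_by_grid = {}
    for gid in gmap:
        sub = [e for e in ok if e.grid_id == gid]
        ref_by_grid[gid] = (float(np.median([e.g0 for e in sub])),
                            float(np.median([e.sigma_m for e in sub]))) if sub else ref_all
    for e in rows:
        if "non_identifiable" not in e.flags or e.n == 0:
            continue
        g0_ref, sig_ref = ref_by_grid[e.grid_id]
        nocc = occ_by_session[(e.year, e.primary, e.grid_id)]
        a = esa_from_params(gmap[e.grid_id], masks[e.grid_id], g0_ref, sig_ref, nocc)
        e.density = e.n / a
        e.se = float(np.sqrt(e.n) / a)
        cv2 = (e.se / e.density) ** 2
        w = float(np.exp(1.96 * np.sqrt(np.log(1 + cv2))))
        e.lo95, e.hi95 = e.density / w, e.density * w
        e.g0, e.sigma_m = g0_ref, sig_ref
        e.flags.append("detection_from_reference")
    return pd.DataFrame([
        dict(year=e.year, primary=e.primary, grid_id=e.grid_id, sexage=e.sexage,
             n=e.n, g0=e.g0, sigma_m=e.sigma_m, density_ha=e.density, se=e.se,
             lo95=e.lo95, hi95=e.hi95, pooled_flag=e.pooled,
             converged_flag=e.converged, flags=";".join(map(str, e.flags)))
        for e in rows
    ])
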