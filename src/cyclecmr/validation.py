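"""Parameter-recovery studies: the package's own acceptance surface.

Every estimator is validated against the synthetic-population generator:
simulate data with known truth, run the estimator, measure bias, coverage or
sign agreement.  These studies are what the acceptance script and the
acceptance test suite run; their default problem sizes are chosen to finish
on a single CPU in minutes while keeping Monte-Carlo error well below the
tolerances being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._numutil import expit, logit
from .datamodel import TrapGrid, build_annual_histories, build_session_histories
from .robust import ErroredPoint, bootstrap_regression, huber_fit
from .secr import build_mask, derive_density, estimate_all_sessions, fit_conditional
from .simulate import SimulationTruth, TrueIndividual, simulate_detections, simulate_study, default_grids
from .survival import (CJSData, SurvivalDesign, fit_cjs, monthly_survival_table,
                       survival_density_regression)

__all__ = ["secr_recovery_study", "twoaxis_regression_study", "cjs_recovery_study",
           "cjs_selection_study", "negbin_recovery_study", "huber_ols_agreement",
           "end_to_end_sign_study"]


def _uniform_population(rng, grid: TrapGrid, density_ha: float, buffer_m=100.0):
    xy = grid.station_xy()
    lo = xy.min(axis=0) - buffer_m
    hi = xy.max(axis=0) + buffer_m
    area_ha = (hi[0] - lo[0]) * (hi[1] - lo[1]) / 1e4
    n = rng.poisson(density_ha * area_ha)
    return [TrueIndividual(f"i{k:04d}", "F", "adult",
                           (float(rng.uniform(lo[0], hi[0])),
                            float(rng.uniform(lo[1], hi[1]))), 40.0)
            for k in range(n)]


def secr_recovery_study(n_sessions: int = 200, density_ha: float = 5.0,
                        g0: float = 0.3, sigma_m: float = 15.0,
                        n_occasions: int = 6, mask_spacing_m: float = 15.0,
                        seed: int = 0) -> dict:
    """Density recovery: relative bias of D-hat and 95% CI coverage.

    Simulates closed sessions on a 12x12 grid at known density, fits the
    conditional SECR likelihood, and derives Horvitz-Thompson densities.
    """
    rng = np.random.default_rng(seed)
    grid = TrapGrid("wet", "wet", 12, 12)
    mask = build_mask(grid, 100.0, mask_spacing_m)
    truth = SimulationTruth(g0=g0, sigma_m=sigma_m)
    rel, cover, g0s, sigs = [], [], [], []
    for _ in range(n_sessions):
        inds = _uniform_population(rng, grid, density_ha)
        events = simulate_detections(inds, grid, n_occasions, truth, rng,
                                     sigma_override=sigma_m)
        if not events:
            continue
        hs = build_session_histories(events, grid, n_occasions=n_occasions)
        fit = fit_conditional(hs, grid, mask)
        est = derive_density(fit, len(hs), mask, grid=grid)
        rel.append(est.density / density_ha - 1.0)
        cover.append(est.lo95 <= density_ha <= est.hi95)
        g0s.append(fit.g0)
        sigs.append(fit.sigma_m)
    return dict(n=len(rel), rel_bias=float(np.mean(rel)),
                coverage=float(np.mean(cover)), mean_g0=float(np.mean(g0s)),
                mean_sigma_m=float(np.mean(sigs)))


def _errored_points(rng, n, slope, intercept=-1.0, se_y=0.04, se_x_rel=0.15,
                    resid_sd=0.12):
    pts = []
    for _ in range(n):
        x = float(np.exp(rng.uniform(np.log(0.05), np.log(9.0))))
        y_true = float(expit(intercept + slope * x + rng.normal(0, resid_sd)))
        y_obs = float(expit(logit(y_true)
                            + rng.normal(0, se_y / (y_true * (1 - y_true)))))
        x_obs = float(x * np.exp(rng.normal(0, se_x_rel)))
        pts.append(ErroredPoint(x=x_obs, y=y_obs, se_x=se_x_rel * x, se_y=se_y))
    return pts


def twoaxis_regression_study(slope: float = 0.05, n_meta: int = 100, B: int = 500,
                             n_points: int = 30, seed: int = 0) -> dict:
    """Coverage (truth in the 95% CI) and zero-exclusion rate of the
    two-axis error-propagation bootstrap, over independent meta-replicates."""
    rng = np.random.default_rng(seed)
    covered, excl = 0, 0
    for rep in range(n_meta):
        pts = _errored_points(rng, n_points, slope)
        res = bootstrap_regression(pts, B=B, seed=int(rng.integers(2**31)),
                                   include_group=False)
        i = res.terms.index("density")
        covered += res.lo95[i] <= slope <= res.hi95[i]
        excl += not (res.lo95[i] <= 0.0 <= res.hi95[i])
    return dict(n_meta=n_meta, coverage=covered / n_meta,
                zero_exclusion_rate=excl / n_meta)


def huber_ols_agreement(n_rep: int = 50, n: int = 200, seed: int = 0) -> dict:
    """Mean slope difference between Huber and OLS on clean Gaussian data,
    in units of the OLS slope SE."""
    rng = np.random.default_rng(seed)
    diffs, ses = [], []
    for _ in range(n_rep):
        x = rng.uniform(0, 10, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        X = np.column_stack([np.ones_like(x), x])
        bh = huber_fit(X, y)
        bo, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ bo
        ses.append(np.sqrt(r @ r / (n - 2) * np.linalg.inv(X.T @ X)[1, 1]))
        diffs.append(bh[1] - bo[1])
    return dict(mean_abs_diff_per_se=float(abs(np.mean(diffs)) / np.mean(ses)))


def _simulate_cjs(rng, n, T, phi, p, year=2010):
    from .datamodel import AnnualHistory

    classes = sorted(phi)
    dt = 20.0 if year <= 2007 else 30.0
    hists = []
    for i in range(n):
        cls = classes[i % len(classes)]
        sex = cls.split("_")[1]
        pres = np.zeros(T, dtype=int)
        pres[0] = 1
        alive = True
        for t in range(1, T):
            alive = alive and (rng.random() < phi[cls] ** (dt / 30.0))
            if alive and rng.random() < p[sex]:
                pres[t] = 1
        hists.append(AnnualHistory(f"i{i:04d}", year, "wet", pres, cls, "wet"))
    return hists


def cjs_recovery_study(n: int = 600, T: int = 3, seed: int = 0) -> dict:
    """Recovery of sex-specific monthly apparent survival (0.46 F / 0.29 M)."""
    rng = np.random.default_rng(seed)
    phi = {"adult_female": 0.46, "adult_male": 0.29}
    p = {"female": 0.88, "male": 1.0}
    hists = _simulate_cjs(rng, n, T, phi, p)
    m = fit_cjs(CJSData(hists), SurvivalDesign(("sexage",), ("sex",)))
    tab = monthly_survival_table(m)
    by = tab.groupby("sexage")["phi_monthly"].mean()
    pcap = tab.groupby("sexage")["p_capture"].mean()
    return dict(n=n, phi_adult_female=float(by["adult_female"]),
                phi_adult_male=float(by["adult_male"]),
                p_female=float(pcap["adult_female"]),
                p_male=float(pcap["adult_male"]))


def cjs_selection_study(n_rep: int = 50, n: int = 320, seed: int = 0) -> dict:
    """How often AICc selection recovers the generating survival structure."""
    from .survival import fit_model_set

    rng = np.random.default_rng(seed)
    phi = {"adult_female": 0.46, "adult_male": 0.29,
           "juvenile_female": 0.50, "juvenile_male": 0.22}
    p = {"female": 0.88, "male": 1.0}
    designs = [SurvivalDesign(()), SurvivalDesign(("sexage",)),
               SurvivalDesign(("sexage", "primary"))]
    hits = 0
    for _ in range(n_rep):
        hists = _simulate_cjs(rng, n, 3, phi, p)
        models, sel = fit_model_set(hists, designs, compute_vcov_selected=False)
        hits += models[sel].design.phi_effects == ("sexage",)
    return dict(n_rep=n_rep, recovery_rate=hits / n_rep)


def negbin_recovery_study(n_rep: int = 100, n: int = 400, slope: float = -0.08,
                          seed: int = 0) -> dict:
    """CI coverage of the negative-binomial density slope (offset model)."""
    from .behavior import negbin_fit

    rng = np.random.default_rng(seed)
    hits, est = 0, []
    for _ in range(n_rep):
        d = rng.uniform(0, 9, n)
        sex = rng.choice(["M", "F"], n)
        ncap = rng.integers(2, 8, n)
        mu = np.exp(3.6 + slope * d + 0.3 * (sex == "M")) * ncap
        y = rng.negative_binomial(1 / 0.4, 1 / (1 + 0.4 * mu))
        df = pd.DataFrame(dict(max_dist_m=y, density=d, sex=sex,
                               n_captures=ncap))
        fit = negbin_fit(df, terms=("density", "sex"))
        lo, hi = fit.ci95("density")
        hits += lo <= slope <= hi
        est.append(fit.coef("density"))
    return dict(n_rep=n_rep, coverage=hits / n_rep,
                mean_slope=float(np.mean(est)))


def end_to_end_sign_study(n_seeds: int = 6, base_seed: int = 0,
                          B_regression: int = 300,
                          mask_spacing_m: float = 15.0) -> dict:
    """Full synthetic 16-year studies: does the analysis reproduce the
    qualitative density-dependence pattern it was parameterised with?

    Checks, per seed: positive adult-female-proportion slope, positive adult
    (F and M) survival-density slopes, negative movement-distance slope.
    Returns per-seed sign indicators and the overall fraction correct.
    """
    from . import composition
    from .behavior import compute_distances, movement_frame, negbin_fit
    from .pipeline import _annual_density, _delta_proportion_se, _grid_level_map, _total_density

    grids = default_grids()
    gmap = {g.grid_id: g for g in grids}
    per_seed = []
    for k in range(n_seeds):
        seed = base_seed + k
        truth = SimulationTruth(seed=seed)
        events, rec = simulate_study(truth)
        den = estimate_all_sessions(events, grids, mask_spacing_m=mask_spacing_m)
        tot = _total_density(den)
        signs = {}
        # adult-female proportion vs density
        props = composition.proportions_from_densities(den)
        props = _delta_proportion_se(props, den)
        merged = props.drop(columns=["total_density_ha"], errors="ignore").merge(
            tot, on=["year", "primary", "grid_id"])
        sub = merged[(merged.sexage == "adult_female")
                     & np.isfinite(merged.proportion)
                     & (merged.total_density_ha > 0)]
        pts = [ErroredPoint(x=r.total_density_ha, y=r.proportion,
                            se_x=float(np.nan_to_num(r.se_total)),
                            se_y=float(np.nan_to_num(r.se)),
                            group=str(gmap[r.grid_id].covariate_level(int(r.year))))
               for r in sub.itertuples(index=False)]
        res = bootstrap_regression(pts, B=B_regression, seed=seed + 100)
        signs["prop_adult_female_slope"] = res.coef("density")
        # survival vs density (year-varying design)
        ann = build_annual_histories(events, grids)
        m = fit_cjs(CJSData(ann), SurvivalDesign(
            ("sexage", "primary", "year", "sexage_x_primary", "grid")))
        tab = monthly_survival_table(m)
        lvl = _grid_level_map(grids, den)
        for cls in ("adult_female", "adult_male"):
            s = tab[(tab.sexage == cls) & (tab.flag != "boundary")].copy()
            s["grid_id"] = [lvl.get((int(r.year), r.grid), r.grid)
                            for r in s.itertuples(index=False)]
            s["year"] = s["year"].astype(int)
            s["primary"] = s["transition"].astype(int)
            s = s.merge(tot, on=["year", "primary", "grid_id"], how="inner")
            s = s.rename(columns={"total_density_ha": "density_ha",
                                  "se_total": "se_density"})
            r = survival_density_regression(s, B=B_regression, seed=seed + 200)
            signs[f"phi_{cls}_slope"] = r.coef("density")
        # movement vs annual density
        ad = _annual_density(den)
        mdf = movement_frame(compute_distances(events, grids), ad).dropna(subset=["density"])
        fit = negbin_fit(mdf, terms=("density", "sex", "age"))
        signs["movement_slope"] = fit.coef("density")
        correct = dict(
            prop_adult_female=signs["prop_adult_female_slope"] > 0,
            phi_adult_female=signs["phi_adult_female_slope"] > 0,
            phi_adult_male=signs["phi_adult_male_slope"] > 0,
            movement=signs["movement_slope"] < 0,
        )
        per_seed.append(dict(seed=seed, slopes=signs, correct=correct))
    flat = [v for r in per_seed for v in r["correct"].values()]
    return dict(n_seeds=n_seeds, per_seed=per_seed,
                fraction_correct=float(np.mean(flat)))
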