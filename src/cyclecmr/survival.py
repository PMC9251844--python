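"""Cormack-Jolly-Seber apparent survival among primary periods.

Apparent survival (surviving *and* staying on the grid) is estimated from
presence/absence across the primary periods of each summer, conditioning on
first capture.  Primary periods are separated by 20 days in the early study
years and 30 days afterwards; interval survival is parameterised through a
*monthly* survival probability, phi_interval = phi_monthly^(dt/30), so
estimates from both schedules are directly comparable.

Candidate models combine sex-age group, primary-period, year and grid
effects on survival (logit-linear, treatment coding) with a sex effect on
recapture probability; selection uses AICc and the simplest-model rule
shared with the behavioural analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._numutil import expit, numeric_hessian, safe_vcov
from .datamodel import AnnualHistory
from .robust import ErroredPoint, RegressionResult, bootstrap_regression
from .selection import aicc, select_simplest

__all__ = ["SurvivalDesign", "SurvivalModel", "CJSData", "cjs_negloglik",
           "fit_cjs", "fit_model_set", "default_candidate_designs",
           "monthly_survival_table", "survival_density_regression"]

PHI_EFFECTS = ("sexage", "primary", "year", "grid", "sexage_x_primary")
BOUNDARY_TOL = 1e-3


@dataclass(frozen=True)
class SurvivalDesign:
    phi_effects: tuple = ()
    p_effects: tuple = ("sex",)
    name: str = ""

    def label(self) -> str:
        phi = "+".join(self.phi_effects) or "."
        p = "+".join(self.p_effects) or "."
        return self.name or f"phi({phi}) p({p})"


class CJSData:
    """Padded arrays for fast CJS likelihood evaluation on annual histories."""

    def __init__(self, histories: list[AnnualHistory]):
        histories = [h for h in histories if len(h.presence) >= 2]
        if not histories:
            raise ValueError("need histories spanning at least 2 primary periods")
        self.histories = histories
        self.n = len(histories)
        self.Tmax = max(len(h.presence) for h in histories)
        self.Y = np.zeros((self.n, self.Tmax), dtype=int)
        self.Ti = np.array([len(h.presence) for h in histories])
        self.f = np.empty(self.n, dtype=int)
        self.l = np.empty(self.n, dtype=int)
        for i, h in enumerate(histories):
            self.Y[i, :len(h.presence)] = h.presence
            seen = np.flatnonzero(h.presence)
            self.f[i], self.l[i] = seen[0], seen[-1]
        if np.all(self.l == self.f):
            raise ValueError("no individual was ever recaptured across primaries;"
                             " survival is not identifiable")
        # per-transition interval length (days)
        self.dt = np.zeros((self.n, self.Tmax - 1))
        for i, h in enumerate(histories):
            self.dt[i, :self.Ti[i] - 1] = 20.0 if h.year <= 2007 else 30.0
        self.valid_tr = np.arange(self.Tmax - 1)[None, :] < (self.Ti - 1)[:, None]
        # covariate frames
        self.cov = pd.DataFrame(dict(
            sexage=[h.sexage for h in histories],
            sex=[h.sexage.split("_")[1] for h in histories],
            year=[str(h.year) for h in histories],
            grid=[h.grid_level for h in histories],
        ))
        self.n_released = self.n

    def design_matrices(self, design: SurvivalDesign):
        """(X_phi, X_p) with rows (individual x transition) and (individual x occasion)."""
        X_phi = _build_design(self.cov, design.phi_effects, self.Tmax - 1, "transition")
        X_p = _build_design(self.cov, design.p_effects, self.Tmax, "occasion")
        return X_phi, X_p


def _build_design(cov: pd.DataFrame, effects: tuple, n_time: int, time_name: str):
    n = len(cov)
    long = cov.loc[cov.index.repeat(n_time)].reset_index(drop=True)
    long[time_name] = np.tile(np.arange(1, n_time + 1).astype(str), n)
    cols = [np.ones(len(long))]
    names = ["intercept"]

    def add_factor(key):
        col = long[time_name] if key == "primary" else long[key]
        dm = pd.get_dummies(col, prefix=key, drop_first=True, dtype=float)
        for c in dm.columns:
            cols.append(dm[c].to_numpy())
            names.append(c)
        return dm

    dms = {}
    for eff in effects:
        if eff == "sexage_x_primary":
            continue
        if eff == "primary":
            dms["primary"] = add_factor("primary")
        elif eff in ("sexage", "sex", "year", "grid"):
            dms[eff] = add_factor(eff)
        else:
            raise ValueError(f"unknown effect {eff!r}")
    if "sexage_x_primary" in effects:
        if "sexage" not in dms:
            dms["sexage"] = add_factor("sexage")
        if "primary" not in dms:
            dms["primary"] = add_factor("primary")
        for a in dms["sexage"].columns:
            for b in dms["primary"].columns:
                cols.append((dms["sexage"][a] * dms["primary"][b]).to_numpy())
                names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    return X, names, long


@dataclass
class SurvivalModel:
    design: SurvivalDesign
    beta_phi: np.ndarray
    beta_p: np.ndarray
    loglik: float
    n_params: int
    aicc: float
    converged: bool
    data: CJSData
    phi_terms: list
    p_terms: list
    vcov: np.ndarray | None = None
    name: str = ""

    def phi_monthly_matrix(self) -> np.ndarray:
        (X_phi, _, _), _ = self.data.design_matrices(self.design)
        return expit(X_phi @ self.beta_phi).reshape(self.data.n, self.data.Tmax - 1)


def _unpack(params, k_phi):
    return params[:k_phi], params[k_phi:]


def cjs_negloglik(params: np.ndarray, data: CJSData, X_phi, X_p) -> float:
    """Negative CJS log-likelihood, conditioned on first capture.

    ``X_phi`` has one row per (individual, transition) and parameterises
    logit monthly survival; interval survival is phi_monthly^(dt/30).
    ``X_p`` has one row per (individual, occasion) for recapture probability.
    """
    n, T = data.n, data.Tmax
    k_phi = X_phi.shape[1]
    b_phi, b_p = _unpack(params, k_phi)
    phi_m = expit(X_phi @ b_phi).reshape(n, T - 1)
    phi = np.clip(phi_m, 1e-12, 1 - 1e-12) ** (data.dt / 30.0)
    p = np.clip(expit(X_p @ b_p).reshape(n, T), 1e-12, 1 - 1e-12)
    valid = data.valid_tr
    phi = np.where(valid, phi, 0.0)
    # chi[i, t]: P(never seen after t | alive at t)
    chi = np.ones((n, T))
    for t in range(T - 2, -1, -1):
        val = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - p[:, t + 1]) * chi[:, t + 1]
        chi[:, t] = np.where(valid[:, t], val, 1.0)
    tidx = np.arange(T - 1)[None, :]
    in_core = (tidx >= data.f[:, None]) & (tidx < data.l[:, None])
    seen_next = data.Y[:, 1:] == 1
    trans_ll = np.where(
        in_core,
        np.log(np.where(in_core, phi, 1.0))
        + np.where(seen_next, np.log(p[:, 1:]), np.log1p(-p[:, 1:])),
        0.0,
    )
    ll = trans_ll.sum() + np.log(chi[np.arange(n), data.l]).sum()
    return -float(ll)


def fit_cjs(histories_or_data, design: SurvivalDesign, compute_vcov: bool = True) -> SurvivalModel:
    """Maximum-likelihood CJS fit for one design."""
    data = histories_or_data if isinstance(histories_or_data, CJSData) else CJSData(histories_or_data)
    (X_phi, phi_terms, _), (X_p, p_terms, _) = data.design_matrices(design)
    k_phi, k_p = X_phi.shape[1], X_p.shape[1]
    x0 = np.zeros(k_phi + k_p)

    def f(params):
        return cjs_negloglik(params, data, X_phi, X_p)

    res = minimize(f, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8})
    vcov = None
    if compute_vcov:
        vcov = safe_vcov(numeric_hessian(f, res.x, eps=1e-4))
    k = k_phi + k_p
    ll = -float(res.fun)
    return SurvivalModel(
        design=design, beta_phi=res.x[:k_phi], beta_p=res.x[k_phi:],
        loglik=ll, n_params=k, aicc=aicc(ll, k, data.n_released),
        converged=bool(res.success), data=data, phi_terms=phi_terms,
        p_terms=p_terms, vcov=vcov, name=design.label(),
    )


def default_candidate_designs() -> list[SurvivalDesign]:
    return [
        SurvivalDesign(()),
        SurvivalDesign(("sexage",)),
        SurvivalDesign(("sexage", "grid")),
        SurvivalDesign(("sexage", "primary")),
        SurvivalDesign(("sexage", "primary", "sexage_x_primary")),
        SurvivalDesign(("sexage", "primary", "sexage_x_primary", "grid")),
        SurvivalDesign(("sexage", "primary", "year", "sexage_x_primary", "grid")),
    ]


def fit_model_set(histories, candidate_designs=None, compute_vcov_selected: bool = True):
    """Fit every candidate design and apply the simplest-model AICc rule.

    Returns ``(models, selected_index)``; non-convergent fits stay in the
    list but are excluded from selection.  AICc uses the number of released
    individuals as the effective sample size.
    """
    data = CJSData(histories)
    designs = candidate_designs or default_candidate_designs()
    models = []
    for d in designs:
        try:
            m = fit_cjs(data, d, compute_vcov=False)
        except Exception:
            continue
        models.append(m)
    if not models:
        raise RuntimeError("no candidate design could be fitted")
    ok = [m if m.converged else _inf_model(m) for m in models]
    sel = select_simplest(ok)
    if compute_vcov_selected:
        models[sel] = fit_cjs(data, models[sel].design, compute_vcov=True)
    return models, sel


def _inf_model(m):
    import copy

    m2 = copy.copy(m)
    m2.aicc = np.inf
    return m2


def monthly_survival_table(model: SurvivalModel) -> pd.DataFrame:
    """Back-transformed monthly survival per design cell with Wald 95% CIs.

    Boundary estimates (phi of 0 or 1 to numerical precision) are flagged:
    they occur in years where no animal was ever recaptured between
    primaries.  Capture probabilities are reported per group alongside.
    """
    data = model.data
    (X_phi, _, long_phi), (X_p, _, long_p) = data.design_matrices(model.design)
    eta = X_phi @ model.beta_phi
    phi = expit(eta)
    keys = ["sexage", "year", "grid", "transition"]
    frame = long_phi[keys].copy()
    frame["phi_monthly"] = phi
    if model.vcov is not None:
        V = model.vcov[:len(model.beta_phi), :len(model.beta_phi)]
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X_phi, V, X_phi), 0.0))
        frame["lo95"] = expit(eta - 1.96 * se_eta)
        frame["hi95"] = expit(eta + 1.96 * se_eta)
        frame["se_phi"] = se_eta * phi * (1 - phi)
    else:
        frame["lo95"] = frame["hi95"] = frame["se_phi"] = np.nan
    p_eta = X_p @ model.beta_p
    long_p = long_p.copy()
    long_p["p_capture"] = expit(p_eta)
    pmap = long_p.groupby("sex")["p_capture"].mean()
    frame["sex"] = frame["sexage"].str.split("_").str[1]
    frame["p_capture"] = frame["sex"].map(pmap)
    out = (frame.groupby(["sexage", "year", "grid", "transition"], as_index=False)
           [["phi_monthly", "lo95", "hi95", "se_phi", "p_capture"]].mean())
    out["flag"] = np.where(
        (out["phi_monthly"] < BOUNDARY_TOL) | (out["phi_monthly"] > 1 - BOUNDARY_TOL),
        "boundary", "")
    return out


def survival_density_regression(
    survival_table: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    include_group: bool = True,
) -> RegressionResult:
    """Robust two-axis regression of monthly survival on density.

    Expects columns ``phi_monthly``, ``se_phi``, ``density_ha``, ``se_density``
    (and optionally ``grid``) with one row per year x group x grid pairing of
    survival between primaries t and t+1 against density at t.  Boundary
    survival values (exactly 0/1) cannot live on the logit axis and are
    excluded, as are rows with missing inputs.
    """
    df = survival_table.copy()
    if df.empty:
        raise ValueError("empty survival table")
    keep = (
        np.isfinite(df["phi_monthly"]) & np.isfinite(df["density_ha"])
        & (df["phi_monthly"] > BOUNDARY_TOL) & (df["phi_monthly"] < 1 - BOUNDARY_TOL)
    )
    df = df[keep]
    if len(df) < 3:
        raise ValueError("too few usable survival-density pairs")
    pts = [
        ErroredPoint(x=row.density_ha, y=row.phi_monthly,
                     se_x=float(getattr(row, "se_density", 0.0) or 0.0),
                     se_y=float(getattr(row, "se_phi", 0.0) or 0.0),
                     group=str(getattr(row, "grid", "")))
        for row in df.itertuples(index=False)
    ]
    return bootstrap_regression(pts, B=B, seed=seed, response="phi_monthly",
                                y_link="logit", include_group=include_group)
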