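"""Movement, reproduction and body-condition models.

Movement: per individual-year, the maximum and mean Euclidean distance from
the first-capture station to every subsequent capture station (0 when all
captures share one trap), modelled with a negative binomial regression with
a log(total captures) offset to control for unequal recapture effort.

Reproduction: adult females only; reproductive state (0/1) per capture is
modelled with a binomial mixed model with an individual random intercept for
the repeated measures.

Body condition: daily change in body mass between *consecutive* primary
periods (within-primary masses averaged, pregnant females excluded),
modelled with linear mixed models always containing initial body mass.

All three analyses share the AICc simplest-model selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import roots_hermitenorm

from ._numutil import expit, numeric_hessian, safe_vcov
from .datamodel import CaptureEvent, TrapGrid, first_capture_class
from .selection import aicc, select_simplest

__all__ = [
    "MovementRecord", "compute_distances", "negbin_fit", "negbin_model_set",
    "ReproObservation", "build_repro_observations", "glmm_binomial_fit",
    "MassChangeRecord", "compute_mass_change", "lmm_mass_fit", "lmm_model_set",
]


# ---------------------------------------------------------------------------
# Movement

@dataclass
class MovementRecord:
    individual_id: str
    year: int
    grid_id: str
    sex: str
    age: str
    max_dist_m: float
    mean_dist_m: float
    n_captures: int


def compute_distances(events: list[CaptureEvent], grids: list[TrapGrid]) -> list[MovementRecord]:
    """One movement record per individual-year, pooling all primary periods.

    Distances run from the station of first capture to each subsequent
    capture station; individuals only ever caught at one trap get 0.
    """
    gmap = {g.grid_id: g for g in grids}
    by_iy: dict[tuple[str, int], list[CaptureEvent]] = {}
    for e in events:
        by_iy.setdefault((e.individual_id, e.year), []).append(e)
    out = []
    for (ind, year), evs in sorted(by_iy.items()):
        evs = sorted(evs, key=lambda e: (e.primary, e.occasion))
        grid = gmap[evs[0].grid_id]
        x0, y0 = evs[0].xy(grid)
        dists = [np.hypot(e.xy(grid)[0] - x0, e.xy(grid)[1] - y0) for e in evs[1:]]
        cls = first_capture_class(evs)
        if cls == "unknown":
            continue
        age, _, sexword = cls.partition("_")
        out.append(MovementRecord(
            individual_id=ind, year=year, grid_id=grid.grid_id,
            sex=evs[0].sex, age=age,
            max_dist_m=float(max(dists)) if dists else 0.0,
            mean_dist_m=float(np.mean(dists)) if dists else 0.0,
            n_captures=len(evs),
        ))
    return out


def movement_frame(records: list[MovementRecord],
                   annual_density: pd.Series | dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if annual_density is not None:
        ad = pd.Series(annual_density)
        df["density"] = df["year"].map(ad)
    return df


@dataclass
class FixedModelFit:
    """A fixed-effects (GLM-family) fit with AICc, for the candidate-set machinery."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_params: int
    aicc: float
    name: str = ""
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def ci95(self, term: str):
        i = self.terms.index(term)
        return (float(self.beta[i] - 1.96 * self.se[i]),
                float(self.beta[i] + 1.96 * self.se[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(term=self.terms, estimate=self.beta, se=self.se,
                                 lo95=self.beta - 1.96 * self.se,
                                 hi95=self.beta + 1.96 * self.se))


def _design_from_terms(df: pd.DataFrame, terms: tuple) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    dms = {}

    def factor(key):
        if key not in dms:
            dms[key] = pd.get_dummies(df[key], prefix=key, drop_first=True, dtype=float)
        return dms[key]

    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            da = factor(a) if df[a].dtype == object else None
            db = factor(b) if df[b].dtype == object else None
            if da is not None and db is not None:
                for ca in da.columns:
                    for cb in db.columns:
                        cols.append((da[ca] * db[cb]).to_numpy())
                        names.append(f"{ca}:{cb}")
            elif da is not None:
                for ca in da.columns:
                    cols.append((da[ca] * df[b]).to_numpy())
                    names.append(f"{ca}:{b}")
            elif db is not None:
                for cb in db.columns:
                    cols.append((df[a] * db[cb]).to_numpy())
                    names.append(f"{a}:{cb}")
            else:
                cols.append((df[a] * df[b]).to_numpy())
                names.append(t)
        elif df[t].dtype == object:
            dm = factor(t)
            for c in dm.columns:
                cols.append(dm[c].to_numpy())
                names.append(c)
        else:
            cols.append(df[t].to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names


def negbin_fit(df: pd.DataFrame, response: str = "max_dist_m",
               terms: tuple = ("density", "sex:age"),
               offset_col: str = "n_captures") -> FixedModelFit:
    """Negative binomial regression of (integer-metre) distance with offset.

    The response is rounded to the nearest metre; the offset is the log of
    the total number of captures.  The dispersion parameter is estimated by
    maximum likelihood (NB2), and counts toward the AICc parameter total.
    """
    y = np.round(df[response].to_numpy(dtype=float)).astype(int)
    if np.all(y == 0):
        raise ValueError("all distances are zero; negative binomial is degenerate")
    X, names = _design_from_terms(df, terms)
    offset = np.log(df[offset_col].to_numpy(dtype=float))
    model = sm.NegativeBinomial(y, X, offset=offset)
    res = model.fit(disp=False, maxiter=200)
    k = len(res.params)  # includes alpha
    ll = float(res.llf)
    return FixedModelFit(
        terms=names, beta=np.asarray(res.params[:-1]), se=np.asarray(res.bse[:-1]),
        loglik=ll, n_params=k, aicc=aicc(ll, k, len(y)),
        name=f"{response} ~ {' + '.join(terms) or '1'}",
        extra={"alpha": float(res.params[-1])},
    )


DEFAULT_MOVEMENT_CANDIDATES = (
    (),
    ("density",),
    ("density", "sex", "age"),
    ("density", "sex", "age", "sex:age"),
    ("density", "sex", "age", "sex:age", "grid_id"),
    ("sex", "age", "sex:age"),
)


def negbin_model_set(df: pd.DataFrame, response: str = "max_dist_m",
                     candidates=DEFAULT_MOVEMENT_CANDIDATES):
    models = []
    for terms in candidates:
        try:
            models.append(negbin_fit(df, response=response, terms=terms))
        except Exception:
            continue
    if not models:
        raise RuntimeError("no movement model could be fitted")
    return models, select_simplest(models)


# ---------------------------------------------------------------------------
# Reproduction (binomial GLMM, scalar random intercept)

@dataclass
class ReproObservation:
    individual_id: str
    reproductive: int
    density: float
    primary: int
    grid: str
    year: int


def build_repro_observations(events: list[CaptureEvent], grids: list[TrapGrid],
                             density_by_session: dict | None = None,
                             first_year: int = 2009) -> list[ReproObservation]:
    """Adult-female reproductive-state observations (one per capture).

    Only females classified adult at first capture and with a recorded
    reproductive state from ``first_year`` onward enter the dataset.
    """
    gmap = {g.grid_id: g for g in grids}
    by_iy: dict[tuple[str, int], list[CaptureEvent]] = {}
    for e in events:
        by_iy.setdefault((e.individual_id, e.year), []).append(e)
    out = []
    for (ind, year), evs in sorted(by_iy.items()):
        if year < first_year or evs[0].sex != "F":
            continue
        if first_capture_class(evs) != "adult_female":
            continue
        for e in sorted(evs, key=lambda e: (e.primary, e.occasion)):
            if e.repro not in ("reproductive", "nonreproductive"):
                continue
            d = np.nan
            if density_by_session is not None:
                d = density_by_session.get((e.year, e.primary, e.grid_id), np.nan)
            out.append(ReproObservation(
                individual_id=ind, reproductive=int(e.repro == "reproductive"),
                density=float(d), primary=e.primary,
                grid=gmap[e.grid_id].covariate_level(year), year=year))
    return out


@dataclass
class GLMMFit:
    terms: list
    beta: np.ndarray
    se: np.ndarray
    re_sd: float
    loglik: float
    n_params: int
    aicc: float
    converged: bool = True
    flags: list = field(default_factory=list)
    name: str = ""

    def coef(self, term):
        return float(self.beta[self.terms.index(term)])

    def ci95(self, term):
        i = self.terms.index(term)
        return (float(self.beta[i] - 1.96 * self.se[i]),
                float(self.beta[i] + 1.96 * self.se[i]))


def glmm_binomial_fit(df: pd.DataFrame, response: str = "reproductive",
                      terms: tuple = ("density", "primary", "grid"),
                      group_col: str = "individual_id",
                      n_quad: int = 25,
                      fix_re_sd: float | None = None) -> GLMMFit:
    """Binomial mixed model with a scalar random intercept per individual.

    The marginal likelihood integrates the random intercept by Gauss-Hermite
    quadrature (``n_quad`` nodes), which is exact enough for a scalar effect;
    ``fix_re_sd=0`` collapses to an ordinary binomial GLM.  Complete
    separation is reported via a flag on huge coefficients.
    """
    work = df.copy()
    if work[response].nunique() < 2:
        raise ValueError("response has no variation")
    if "primary" in terms and "primary" in work and work["primary"].dtype != object:
        work["primary"] = work["primary"].astype(str)
    X, names = _design_from_terms(work, terms)
    y = work[response].to_numpy(dtype=float)
    groups, ginv = np.unique(work[group_col], return_inverse=True)
    G = len(groups)
    # roots_hermitenorm integrates f(x) exp(-x^2/2); normalise to N(0,1)
    nodes, weights = roots_hermitenorm(n_quad)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)

    def negll(params):
        beta, log_sd = params[:-1], params[-1]
        sd = np.exp(log_sd)
        eta = X @ beta
        # (N, J) linear predictors
        lp = eta[:, None] + sd * nodes[None, :]
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        # sum within groups -> (G, J)
        ll_g = np.zeros((G, lp.shape[1]))
        np.add.at(ll_g, ginv, ll_obs)
        m = ll_g.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(ll_g - m + logw[None, :]).sum(axis=1))
        return -float(lse.sum())

    k_beta = X.shape[1]
    if fix_re_sd is not None:
        sd_fixed = max(fix_re_sd, 1e-10)

        def negll_fixed(beta):
            return negll(np.append(beta, np.log(sd_fixed)))

        res = minimize(negll_fixed, np.zeros(k_beta), method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-7})
        beta = res.x
        V = safe_vcov(numeric_hessian(negll_fixed, beta))
        ll = -float(res.fun)
        k = k_beta
        re_sd = fix_re_sd
        flags = []
    else:
        x0 = np.append(np.zeros(k_beta), np.log(0.5))
        res = minimize(negll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
        beta = res.x[:-1]
        re_sd = float(np.exp(res.x[-1]))
        Vfull = safe_vcov(numeric_hessian(negll, res.x))
        V = Vfull[:k_beta, :k_beta]
        ll = -float(res.fun)
        k = k_beta + 1
        flags = []
        if re_sd < 1e-4:
            flags.append("re_variance_near_zero")
        # one observation per group leaves the variance unidentified: the
        # log-sd direction is then flat and its curvature-based SE explodes
        if not res.success or not (0 < Vfull[-1, -1] < 25.0):
            flags.append("re_variance_weakly_identified")
    if np.max(np.abs(beta)) > 15:
        flags = list(flags) + ["possible_separation"]
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    return GLMMFit(terms=names, beta=beta, se=se, re_sd=float(re_sd), loglik=ll,
                   n_params=k, aicc=aicc(ll, k, G), converged=bool(res.success),
                   flags=flags, name=f"{response} ~ {' + '.join(terms) or '1'} + (1|ind)")


DEFAULT_REPRO_CANDIDATES = (
    (),
    ("density",),
    ("density", "primary"),
    ("density", "primary", "grid"),
    ("primary", "grid"),
)


def glmm_model_set(df: pd.DataFrame, candidates=DEFAULT_REPRO_CANDIDATES, **kw):
    models = []
    for terms in candidates:
        try:
            models.append(glmm_binomial_fit(df, terms=terms, **kw))
        except Exception:
            continue
    if not models:
        raise RuntimeError("no reproduction model could be fitted")
    return models, select_simplest(models)


# ---------------------------------------------------------------------------
# Daily body-mass change

@dataclass
class MassChangeRecord:
    individual_id: str
    year: int
    grid_id: str
    sex: str
    delta_g_per_day: float
    initial_mass_g: float
    period_pair: str       # "early" (June-July) or "late" (July-August)
    density: float = np.nan


def compute_mass_change(events: list[CaptureEvent],
                        interval_days_by_year=None) -> list[MassChangeRecord]:
    """Daily mass change between consecutive primary periods.

    Within-primary masses are averaged; period pairs that skip a primary are
    ignored; pregnant females are excluded; the divisor is the 20- or 30-day
    interval in force that year.
    """
    if interval_days_by_year is None:
        interval_days_by_year = lambda y: 20.0 if y <= 2007 else 30.0
    elif isinstance(interval_days_by_year, dict):
        d = interval_days_by_year
        interval_days_by_year = lambda y: d[y]
    by_iy: dict[tuple[str, int], list[CaptureEvent]] = {}
    for e in events:
        by_iy.setdefault((e.individual_id, e.year), []).append(e)
    out = []
    for (ind, year), evs in sorted(by_iy.items()):
        if any(e.pregnant for e in evs):
            continue
        per_primary: dict[int, list[float]] = {}
        for e in evs:
            if e.mass_g is not None and np.isfinite(e.mass_g):
                per_primary.setdefault(e.primary, []).append(e.mass_g)
        means = {p: float(np.mean(v)) for p, v in per_primary.items()}
        dt = interval_days_by_year(year)
        n_primaries = max(means) if means else 0
        for p in sorted(means):
            if p + 1 not in means:
                continue
            pair = "early" if p <= n_primaries // 2 else "late"
            out.append(MassChangeRecord(
                individual_id=ind, year=year, grid_id=evs[0].grid_id,
                sex=evs[0].sex,
                delta_g_per_day=(means[p + 1] - means[p]) / dt,
                initial_mass_g=means[p], period_pair=pair))
    return out


def mass_frame(records: list[MassChangeRecord],
               annual_density: pd.Series | dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if annual_density is not None and not df.empty:
        df["density"] = df["year"].map(pd.Series(annual_density))
    return df


@dataclass
class LMMFit:
    terms: list
    beta: np.ndarray
    se: np.ndarray
    re_sd: float
    resid_sd: float
    loglik: float
    n_params: int
    aicc: float
    flags: list = field(default_factory=list)
    name: str = ""

    def coef(self, term):
        return float(self.beta[self.terms.index(term)])

    def ci95(self, term):
        i = self.terms.index(term)
        return (float(self.beta[i] - 1.96 * self.se[i]),
                float(self.beta[i] + 1.96 * self.se[i]))


def lmm_mass_fit(df: pd.DataFrame, terms: tuple = ("initial_mass_g", "period_pair",
                                                   "initial_mass_g:period_pair"),
                 group_col: str = "individual_id", reml: bool = False) -> LMMFit:
    """Linear mixed model for daily mass change with individual random intercept.

    Fitted by ML (default) so AICc comparisons across fixed-effect structures
    are valid.  A singular random-effect variance is flagged and the model is
    effectively an ordinary linear regression.
    """
    X, names = _design_from_terms(df, terms)
    y = df["delta_g_per_day"].to_numpy(dtype=float)
    groups = df[group_col].to_numpy()
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=reml, method="lbfgs",
                                                      maxiter=500)
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        resid_var = float(res.scale)
        ll = float(res.llf)
        flags = ["re_variance_zero"] if re_var < 1e-10 else []
    except (np.linalg.LinAlgError, ValueError):
        # grouping variance on the boundary: the mixed fit degenerates to OLS
        ols = sm.OLS(y, X).fit()
        beta = np.asarray(ols.params)
        se = np.asarray(ols.bse)
        re_var, resid_var = 0.0, float(ols.scale)
        n = len(y)
        ll = float(-0.5 * n * (np.log(2 * np.pi * np.sum(ols.resid**2) / n) + 1))
        flags = ["re_variance_zero"]
    k = X.shape[1] + 2  # + random-intercept variance + residual variance
    return LMMFit(terms=names, beta=beta, se=se,
                  re_sd=float(np.sqrt(max(re_var, 0.0))),
                  resid_sd=float(np.sqrt(resid_var)), loglik=ll, n_params=k,
                  aicc=aicc(ll, k, len(df[group_col].unique())), flags=flags,
                  name=f"delta ~ {' + '.join(terms)} + (1|ind)")


DEFAULT_MASS_CANDIDATES = (
    ("initial_mass_g",),
    ("initial_mass_g", "period_pair"),
    ("initial_mass_g", "period_pair", "initial_mass_g:period_pair"),
    ("initial_mass_g", "period_pair", "initial_mass_g:period_pair", "density"),
    ("initial_mass_g", "density"),
    ("initial_mass_g", "sex"),
)


def lmm_model_set(df: pd.DataFrame, candidates=DEFAULT_MASS_CANDIDATES, **kw):
    models = []
    for terms in candidates:
        try:
            models.append(lmm_mass_fit(df, terms=terms, **kw))
        except Exception:
            continue
    if not models:
        raise RuntimeError("no mass model could be fitted")
    return models, select_simplest(models)
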