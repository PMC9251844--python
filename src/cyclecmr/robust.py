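"""Huber M-estimator regression with a two-axis error-propagating bootstrap.

Demographic quantities arrive as (density, proportion-or-probability) pairs
in which *both* axes carry sampling error.  The regression procedure:

1. resample the paired points with replacement (same sample size);
2. perturb each resampled point by drawing from a normal distribution on the
   link scale -- logit for the response, log for density -- with the
   delta-method SD implied by the point's standard error, then back-transform;
3. fit a robust linear model (Huber M-estimator, IRLS with MAD scale) to
   each perturbed dataset;
4. report the mean coefficients over the B replicates and the 2.5%/97.5%
   quantiles as the 95% confidence interval.

A coefficient is called significant when its interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._numutil import expit, logit

__all__ = ["ErroredPoint", "RegressionResult", "huber_fit", "perturb_dataset",
           "bootstrap_regression"]

HUBER_C = 1.345           # 95% Gaussian efficiency
DEFAULT_B = 2000
Y_CLAMP_N = 200           # boundary clamp: y in [0.5/(N+1), 1-0.5/(N+1)]
X_FLOOR = 0.01            # animals/ha floor before log (local extirpations occur)


@dataclass
class ErroredPoint:
    x: float                # density, animals/ha
    y: float                # proportion or probability
    se_x: float = 0.0
    se_y: float = 0.0
    group: str = ""         # grid covariate level


@dataclass
class RegressionResult:
    terms: list
    beta: np.ndarray        # mean over replicates
    lo95: np.ndarray
    hi95: np.ndarray
    B: int
    n_points: int
    n_failed: int = 0
    response: str = ""
    replicates: np.ndarray | None = None

    def significant(self, term: str) -> bool:
        i = self.terms.index(term)
        return not (self.lo95[i] <= 0.0 <= self.hi95[i])

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(term=self.terms, estimate=self.beta,
                                 lo95=self.lo95, hi95=self.hi95,
                                 B=self.B, n=self.n_points, response=self.response))


def huber_fit(X: np.ndarray, y: np.ndarray, tuning_c: float = HUBER_C,
              max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Huber M-estimator coefficients by iteratively reweighted least squares.

    Scale is re-estimated each iteration as MAD/0.6745 of the residuals.
    Zero-residual (exactly interpolable) data short-circuits to the
    least-squares solution.  Raises on rank-deficient designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more points ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale < 1e-12:
            return beta  # exact interpolation / degenerate scale
        u = np.abs(r) / scale
        w = np.where(u <= tuning_c, 1.0, tuning_c / np.maximum(u, 1e-300))
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


MAX_LINK_SD = 2.0  # cap on the link-scale perturbation SD (numerical guard)


def _link_ses(points: list[ErroredPoint], y_clamp_n: int = Y_CLAMP_N,
              x_floor: float = X_FLOOR):
    """Delta-method SDs on the link scales: se_logit = se_y/(y(1-y)), se_log = se_x/x.

    Link SDs are capped at ``MAX_LINK_SD``: a point whose SE rivals its value
    (coefficient of variation far above 1, as happens for near-extirpation
    densities) would otherwise generate astronomically scattered draws that
    no longer carry information about the point.
    """
    eps = 0.5 / (y_clamp_n + 1)
    y = np.clip([p.y for p in points], eps, 1.0 - eps)
    x = np.maximum([p.x for p in points], x_floor)
    se_y = np.asarray([p.se_y for p in points], dtype=float)
    se_x = np.asarray([p.se_x for p in points], dtype=float)
    se_lx = np.minimum(se_x / x, MAX_LINK_SD)
    se_ly = np.minimum(se_y / (y * (1.0 - y)), MAX_LINK_SD)
    return x, y, se_lx, se_ly


def perturb_dataset(points: list[ErroredPoint], rng: np.random.Generator,
                    y_clamp_n: int = Y_CLAMP_N, x_floor: float = X_FLOOR):
    """Draw one error-propagated replicate of the points.

    y is drawn from Normal(logit(y), se_logit) then inverse-logit, so the
    perturbed response always stays in (0,1); x from Normal(log(x), se_log)
    then exponentiated, staying positive.  Zero SEs return the (clamped)
    input values exactly.
    """
    x, y, se_lx, se_ly = _link_ses(points, y_clamp_n, x_floor)
    xs = np.exp(np.log(x) + rng.standard_normal(len(x)) * se_lx)
    ys = expit(logit(y) + rng.standard_normal(len(y)) * se_ly)
    return xs, ys


def _design(x: np.ndarray, groups: np.ndarray | None, group_levels: list | None):
    cols = [np.ones_like(x), x]
    terms = ["intercept", "density"]
    if group_levels:
        for lev in group_levels[1:]:
            cols.append((groups == lev).astype(float))
            terms.append(f"group[{lev}]")
    return np.column_stack(cols), terms


def bootstrap_regression(
    points: list[ErroredPoint],
    B: int = DEFAULT_B,
    seed: int = 0,
    response: str = "proportion",
    y_link: str = "logit",
    include_group: bool = True,
    tuning_c: float = HUBER_C,
    y_clamp_n: int = Y_CLAMP_N,
    x_floor: float = X_FLOOR,
    keep_replicates: bool = False,
) -> RegressionResult:
    """The two-axis bootstrap: resample pairs, propagate errors, robust-fit.

    The response is modelled on the logit scale by default (proportions and
    survival probabilities live in (0,1)); set ``y_link='identity'`` for an
    unbounded response.  The density covariate enters the mean structure on
    its natural scale; its perturbation happens on the log scale.  Pairs are
    resampled as units together with their grid covariate.
    """
    if len(points) < 3:
        raise ValueError("too few points for regression")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    pts = list(points)
    groups = np.array([p.group for p in pts])
    group_levels = sorted(set(groups)) if include_group and len(set(groups)) > 1 else None
    n = len(pts)
    n_terms = 2 + (len(group_levels) - 1 if group_levels else 0)
    betas = np.full((B, n_terms), np.nan)
    n_failed = 0
    terms = None
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub = [pts[i] for i in idx]
        xs, ys = perturb_dataset(sub, rng, y_clamp_n, x_floor)
        resp = logit(ys) if y_link == "logit" else ys
        X, terms = _design(xs, groups[idx], group_levels)
        try:
            betas[b] = huber_fit(X, resp, tuning_c=tuning_c)
        except Exception:
            n_failed += 1
    ok = betas[np.all(np.isfinite(betas), axis=1)]
    if len(ok) < max(10, B // 10):
        raise RuntimeError(f"bootstrap failed: only {len(ok)}/{B} replicates converged")
    return RegressionResult(
        terms=terms, beta=ok.mean(axis=0),
        lo95=np.quantile(ok, 0.025, axis=0), hi95=np.quantile(ok, 0.975, axis=0),
        B=B, n_points=n, n_failed=n_failed, response=response,
        replicates=ok if keep_replicates else None,
    )
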