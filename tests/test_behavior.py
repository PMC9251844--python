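import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyclecmr.datamodel import CaptureEvent, TrapGrid
from cyclecmr._numutil import expit
from cyclecmr.behavior import (
    compute_distances, compute_mass_change, glmm_binomial_fit, lmm_mass_fit,
    lmm_model_set, negbin_fit,
)


def ev(ind="a", year=2010, primary=1, occ=1, col=0, row=0, sex="F", mass=30.0,
       grid="wet", **kw):
    return CaptureEvent(ind, year, primary, occ, grid, col, row, sex, mass, **kw)


GRID = TrapGrid("wet", "wet", 12, 12)


class TestDistances:
    def test_three_four_five(self):
        # 10-m spacing: captures at (0,0), (30,0), (0,40) -> distances 30 and 40
        grid = TrapGrid("wet", "wet", 12, 12, spacing_m=10.0)
        events = [ev(occ=1, col=0, row=0), ev(occ=2, col=3, row=0),
                  ev(occ=3, col=0, row=4)]
        (r,) = compute_distances(events, [grid])
        assert r.max_dist_m == pytest.approx(40.0)
        assert r.mean_dist_m == pytest.approx(35.0)
        assert r.n_captures == 3

    def test_single_capture_zero(self):
        (r,) = compute_distances([ev()], [GRID])
        assert r.max_dist_m == 0.0 and r.mean_dist_m == 0.0

    def test_same_trap_zero(self):
        events = [ev(occ=o, col=5, row=5) for o in (1, 2, 3)]
        (r,) = compute_distances(events, [GRID])
        assert r.max_dist_m == 0.0

    def test_mean_le_max(self):
        rng = np.random.default_rng(0)
        events = [ev(occ=int(o), col=int(rng.integers(12)), row=int(rng.integers(12)))
                  for o in range(1, 8)]
        (r,) = compute_distances(events, [GRID])
        assert r.mean_dist_m <= r.max_dist_m

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_translation_rotation_invariance(self, seed):
        """Distances depend only on relative station geometry."""
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 12, size=(5, 2))
        events = [ev(occ=i + 1, col=int(c), row=int(r))
                  for i, (c, r) in enumerate(pts)]
        (r0,) = compute_distances(events, [GRID])
        # rotate 90 degrees: (c, r) -> (r, 11-c) preserves pairwise distances
        rot = [ev(occ=i + 1, col=int(r), row=int(11 - c))
               for i, (c, r) in enumerate(pts)]
        (r1,) = compute_distances(rot, [GRID])
        assert r1.max_dist_m == pytest.approx(r0.max_dist_m)
        assert r1.mean_dist_m == pytest.approx(r0.mean_dist_m)

    def test_primaries_pooled_per_year(self):
        events = [ev(occ=1, primary=1, col=0, row=0),
                  ev(occ=1, primary=3, col=6, row=0)]
        (r,) = compute_distances(events, [GRID])
        assert r.max_dist_m == pytest.approx(180.0)


def simulate_negbin(rng, n=600, slope=-0.08, intercept=3.6, alpha=0.4):
    d = rng.uniform(0, 9, n)
    sex = rng.choice(["M", "F"], n)
    age = rng.choice(["adult", "juvenile"], n)
    ncap = rng.integers(2, 8, n)
    mu = np.exp(intercept + slope * d + 0.3 * (sex == "M")) * ncap
    y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    return pd.DataFrame(dict(max_dist_m=y, density=d, sex=sex, age=age,
                             n_captures=ncap, grid_id="wet"))


class TestNegBin:
    def test_poisson_limit(self):
        """On Poisson data the NB dispersion goes to ~0 and coefficients match Poisson."""
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 9, 800)
        ncap = rng.integers(2, 8, 800)
        mu = np.exp(3.0 - 0.08 * d) * ncap
        df = pd.DataFrame(dict(max_dist_m=rng.poisson(mu), density=d,
                               sex="F", age="adult", n_captures=ncap))
        fit = negbin_fit(df, terms=("density",))
        X = np.column_stack([np.ones(len(df)), d])
        pois = sm.GLM(df["max_dist_m"], X, family=sm.families.Poisson(),
                      offset=np.log(ncap)).fit()
        assert fit.beta == pytest.approx(np.asarray(pois.params), abs=1e-3)

    def test_offset_contract(self):
        rng = np.random.default_rng(2)
        df = simulate_negbin(rng)
        fit1 = negbin_fit(df, terms=("density",))
        df2 = df.copy()
        df2["n_captures"] = df2["n_captures"] * 2
        fit2 = negbin_fit(df2, terms=("density",))
        # doubling the offset halves the intercept's implied rate; slope unchanged
        assert fit2.coef("density") == pytest.approx(fit1.coef("density"), abs=1e-6)
        assert fit2.coef("intercept") == pytest.approx(
            fit1.coef("intercept") - np.log(2), abs=1e-6)

    def test_slope_recovery_coverage(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            df = simulate_negbin(rng, n=400)
            fit = negbin_fit(df, terms=("density", "sex"))
            lo, hi = fit.ci95("density")
            hits += lo <= -0.08 <= hi
        assert hits >= 0.85 * 40

    def test_all_zero_rejected(self):
        df = pd.DataFrame(dict(max_dist_m=[0, 0, 0], density=[1, 2, 3],
                               n_captures=[2, 2, 2]))
        with pytest.raises(ValueError):
            negbin_fit(df, terms=("density",))


def simulate_glmm(rng, n_groups=150, slope=-0.09, intercept=1.0, re_sd=0.7):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, re_sd)
        for _ in range(rng.integers(1, 5)):
            x = rng.uniform(0, 9)
            y = rng.random() < expit(intercept + slope * x + b)
            rows.append((f"id{g:04d}", x, int(y), str(rng.integers(1, 4)), "wet"))
    return pd.DataFrame(rows, columns=["individual_id", "density", "reproductive",
                                       "primary", "grid"])


class TestBinomialGLMM:
    def test_matches_lme4_reference(self):
        """Frozen oracle: lme4::glmer (nAGQ=25, bobyqa) on this exact dataset
        gives beta = (0.9794454, -0.1513518), re_sd = 0.8920737, ll = -123.2567."""
        rng = np.random.default_rng(42)
        G = 60
        n_per = rng.integers(1, 6, G)
        b = rng.normal(0, 0.8, G)
        rows = []
        for g in range(G):
            x = rng.uniform(0, 9, n_per[g])
            eta = 0.9 - 0.09 * x + b[g]
            y = (rng.random(n_per[g]) < expit(eta)).astype(int)
            for xi, yi in zip(x, y):
                rows.append((f"id{g:03d}", xi, yi))
        df = pd.DataFrame(rows, columns=["individual_id", "density", "reproductive"])
        fit = glmm_binomial_fit(df, terms=("density",))
        assert fit.beta == pytest.approx([0.9794454, -0.1513518], abs=2e-4)
        assert fit.re_sd == pytest.approx(0.8920737, abs=2e-4)
        assert fit.loglik == pytest.approx(-123.2567, abs=2e-3)

    def test_zero_variance_reduces_to_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        df = simulate_glmm(rng, re_sd=0.0)
        fit = glmm_binomial_fit(df, terms=("density",), fix_re_sd=0.0)
        X = np.column_stack([np.ones(len(df)), df["density"]])
        glm = sm.GLM(df["reproductive"], X, family=sm.families.Binomial()).fit()
        assert fit.beta == pytest.approx(np.asarray(glm.params), abs=1e-6)

    def test_slope_recovery(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(15):
            df = simulate_glmm(rng, n_groups=300)
            fit = glmm_binomial_fit(df, terms=("density",))
            lo, hi = fit.ci95("density")
            hits += lo <= -0.09 <= hi
        assert hits >= 12

    def test_single_obs_per_group_variance_weak(self):
        rng = np.random.default_rng(7)
        rows = [(f"id{i}", rng.uniform(0, 9), int(rng.random() < 0.6))
                for i in range(200)]
        df = pd.DataFrame(rows, columns=["individual_id", "density", "reproductive"])
        fit = glmm_binomial_fit(df, terms=("density",))
        assert (fit.re_sd < 0.5 or "re_variance_near_zero" in fit.flags
                or "re_variance_weakly_identified" in fit.flags)

    def test_no_variation_rejected(self):
        df = pd.DataFrame(dict(individual_id=["a", "b"], density=[1, 2],
                               reproductive=[1, 1]))
        with pytest.raises(ValueError):
            glmm_binomial_fit(df, terms=("density",))


class TestMassChange:
    def test_simple_rate(self):
        events = [ev("a", primary=2, occ=1, mass=30.0),
                  ev("a", primary=3, occ=1, mass=36.0)]
        (r,) = compute_mass_change(events)
        assert r.delta_g_per_day == pytest.approx(0.2)

    def test_twenty_day_divisor_in_early_years(self):
        events = [ev("a", year=2006, primary=1, occ=1, mass=30.0),
                  ev("a", year=2006, primary=2, occ=1, mass=34.0)]
        (r,) = compute_mass_change(events)
        assert r.delta_g_per_day == pytest.approx(4.0 / 20.0)

    def test_non_consecutive_ignored(self):
        events = [ev("a", primary=1, occ=1, mass=30.0),
                  ev("a", primary=3, occ=1, mass=40.0)]
        assert compute_mass_change(events) == []

    def test_within_primary_masses_averaged(self):
        events = [ev("a", primary=2, occ=1, mass=30.0),
                  ev("a", primary=2, occ=4, mass=32.0),
                  ev("a", primary=3, occ=1, mass=37.0)]
        (r,) = compute_mass_change(events)
        assert r.initial_mass_g == pytest.approx(31.0)
        assert r.delta_g_per_day == pytest.approx(0.2)

    def test_pregnant_excluded(self):
        events = [ev("a", primary=1, occ=1, mass=40.0, pregnant=True),
                  ev("a", primary=2, occ=1, mass=44.0)]
        assert compute_mass_change(events) == []


def simulate_mass(rng, n=250, interaction=0.006, re_sd=0.05):
    rows = []
    for i in range(n):
        b = rng.normal(0, re_sd)
        m0 = rng.uniform(15, 60)
        for pair in (["early", "late"] if rng.random() < 0.4 else ["early"]):
            slope = -0.010 if pair == "early" else -0.010 - interaction
            mu = 0.35 + slope * (m0 - 30.0) + (-0.15 if pair == "late" else 0.0)
            rows.append((f"id{i:04d}", mu + b + rng.normal(0, 0.08), m0, pair,
                         rng.uniform(0, 9)))
    return pd.DataFrame(rows, columns=["individual_id", "delta_g_per_day",
                                       "initial_mass_g", "period_pair", "density"])


class TestMassModel:
    def test_zero_variance_matches_ols(self):
        rng = np.random.default_rng(8)
        df = simulate_mass(rng, re_sd=0.0)
        fit = lmm_mass_fit(df, terms=("initial_mass_g",))
        X = np.column_stack([np.ones(len(df)), df["initial_mass_g"]])
        beta_ols, *_ = np.linalg.lstsq(X, df["delta_g_per_day"], rcond=None)
        assert fit.beta == pytest.approx(beta_ols, abs=1e-5)

    def test_interaction_recovery(self):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(10):
            df = simulate_mass(rng, n=400)
            fit = lmm_mass_fit(df)
            term = [t for t in fit.terms if ":" in t][0]
            lo, hi = fit.ci95(term)  # late-vs-early slope difference is -0.006
            hits += lo <= -0.006 <= hi
        assert hits >= 8

    def test_null_density_term_usually_dropped(self):
        rng = np.random.default_rng(10)
        drops = 0
        for rep in range(10):
            df = simulate_mass(rng, n=300)
            models, sel = lmm_model_set(df)
            drops += "density" not in models[sel].terms
        assert drops >= 7
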