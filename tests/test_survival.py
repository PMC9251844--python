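from types import SimpleNamespace

import numpy as np
import pytest

from cyclecmr._numutil import expit, logit
from cyclecmr.datamodel import AnnualHistory
from cyclecmr.selection import aicc, select_simplest, selection_table
from cyclecmr.survival import (
    CJSData, SurvivalDesign, cjs_negloglik, fit_cjs, fit_model_set,
    monthly_survival_table, survival_density_regression,
)

from conftest import simulate_cjs


def histories_2occ(n_released, n_reseen, year=2010):
    hists = []
    for i in range(n_released):
        pres = np.array([1, 1 if i < n_reseen else 0])
        hists.append(AnnualHistory(f"i{i}", year, "wet", pres, "adult_female", "wet"))
    return hists


class TestLikelihood:
    def test_closed_form_phi_when_p_one(self):
        """With p = 1 and 2 occasions, the MLE of interval survival is the return rate."""
        hists = histories_2occ(50, 20)  # 30-day interval: monthly = interval phi
        data = CJSData(hists)
        m = fit_cjs(data, SurvivalDesign((), p_effects=()), compute_vcov=False)
        # p is also estimated; with these data the MLE has phi*p = 0.4 and
        # profile at p -> 1 gives phi = 0.4.  Force p = 1 via a grid check:
        (X_phi, _, _), (X_p, _, _) = data.design_matrices(SurvivalDesign((), p_effects=()))
        best_phi, best = None, np.inf
        for phi in np.linspace(0.01, 0.99, 99):
            val = cjs_negloglik(np.array([logit(phi), 15.0]), data, X_phi, X_p)
            if val < best:
                best, best_phi = val, phi
        assert best_phi == pytest.approx(20 / 50, abs=0.01)

    def test_interval_standardisation_exponent(self):
        """phi_monthly = 0.5 over a 20-day interval gives 0.5^(2/3) ~ 0.63."""
        hists = histories_2occ(10, 5, year=2005)  # 2005: 20-day intervals
        data = CJSData(hists)
        assert np.all(data.dt[:, 0] == 20.0)
        (X_phi, _, _), (X_p, _, _) = data.design_matrices(SurvivalDesign((), p_effects=()))
        # at logit(phi_m)=0 and p=1, -loglik = -[k*log(0.5^(2/3) ) + ...]
        phi_int = 0.5 ** (20 / 30)
        assert phi_int == pytest.approx(0.62996, abs=1e-4)
        nll = cjs_negloglik(np.array([0.0, 30.0]), data, X_phi, X_p)
        expected = -(5 * np.log(phi_int) + 5 * np.log(1 - phi_int))
        assert nll == pytest.approx(expected, abs=1e-4)

    def test_mle_matches_brute_force_grid(self):
        """Optimised (phi, p) equals the maximum of a 101x101 likelihood lattice."""
        rng = np.random.default_rng(13)
        hists = simulate_cjs(rng, n=30, T=3, phi={"adult_female": 0.5},
                             p={"female": 0.8})
        data = CJSData(hists)
        d = SurvivalDesign((), p_effects=())
        (X_phi, _, _), (X_p, _, _) = data.design_matrices(d)
        grid = np.linspace(0.01, 0.99, 101)
        vals = np.array([[cjs_negloglik(np.array([logit(a), logit(b)]), data, X_phi, X_p)
                          for b in grid] for a in grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        m = fit_cjs(data, d, compute_vcov=False)
        step = grid[1] - grid[0]
        assert abs(expit(m.beta_phi[0]) - grid[i]) <= step
        assert abs(expit(m.beta_p[0]) - grid[j]) <= step
        assert -m.loglik <= vals[i, j] + 1e-6

    def test_probabilities_sum_to_one_by_enumeration(self):
        """Over all post-release histories (3 occasions), probabilities sum to 1."""
        params = np.array([0.3, -0.4])  # arbitrary (logit phi, logit p)
        total = 0.0
        for h2 in (0, 1):
            for h3 in (0, 1):
                hist = AnnualHistory("x", 2010, "wet", np.array([1, h2, h3]),
                                     "adult_female", "wet")
                anchor = AnnualHistory("y", 2010, "wet", np.array([1, 1, 1]),
                                       "adult_female", "wet")
                data = CJSData([hist, anchor])
                d = SurvivalDesign((), p_effects=())
                (X_phi, _, _), (X_p, _, _) = data.design_matrices(d)
                nll_pair = cjs_negloglik(params, data, X_phi, X_p)
                data1 = CJSData([anchor, anchor])
                (X1, _, _), (Xp1, _, _) = data1.design_matrices(d)
                nll_anchor = cjs_negloglik(params, data1, X1, Xp1) / 2
                total += np.exp(-(nll_pair - nll_anchor))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_all_singletons_not_identifiable(self):
        hists = [AnnualHistory(f"i{k}", 2010, "wet", np.array([1, 0, 0]),
                               "adult_male", "wet") for k in range(10)]
        with pytest.raises(ValueError, match="identifiable"):
            CJSData(hists)


class TestModelSelection:
    def test_aicc_shift_invariance(self):
        models_a = [SimpleNamespace(aicc=aicc(-100.0, k, 50), n_params=k)
                    for k in (3, 5)]
        models_b = [SimpleNamespace(aicc=aicc(-100.0 + 7.0, k, 50), n_params=k)
                    for k in (3, 5)]
        # shifting every loglik by a constant shifts every AICc equally
        d_a = models_a[1].aicc - models_a[0].aicc
        d_b = models_b[1].aicc - models_b[0].aicc
        assert d_a == pytest.approx(d_b)

    def test_simplest_within_two_units_wins(self):
        models = [SimpleNamespace(aicc=100.0, n_params=8),
                  SimpleNamespace(aicc=101.5, n_params=5)]
        assert select_simplest(models) == 1

    def test_clearly_best_model_wins(self):
        models = [SimpleNamespace(aicc=100.0, n_params=8),
                  SimpleNamespace(aicc=110.0, n_params=5)]
        assert select_simplest(models) == 0

    def test_nested_designs_loglik_ordering(self):
        rng = np.random.default_rng(17)
        hists = simulate_cjs(rng, n=200, T=3)
        data = CJSData(hists)
        small = fit_cjs(data, SurvivalDesign((), ("sex",)), compute_vcov=False)
        big = fit_cjs(data, SurvivalDesign(("sexage",), ("sex",)), compute_vcov=False)
        assert big.loglik >= small.loglik - 1e-6

    def test_generating_design_recovered(self):
        """Strong sex-age differences: that design (or truth-matching simpler
        one) should be selected in most replicates."""
        rng = np.random.default_rng(19)
        phi = {"adult_female": 0.46, "adult_male": 0.29,
               "juvenile_female": 0.50, "juvenile_male": 0.22}
        designs = [SurvivalDesign(()), SurvivalDesign(("sexage",)),
                   SurvivalDesign(("sexage", "primary"))]
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            hists = simulate_cjs(rng, n=320, T=3, phi=phi)
            models, sel = fit_model_set(hists, designs, compute_vcov_selected=False)
            if models[sel].design.phi_effects == ("sexage",):
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_selection_table_marks_one(self):
        models = [SimpleNamespace(aicc=10.0, n_params=2, loglik=-3.0, name="a"),
                  SimpleNamespace(aicc=13.0, n_params=4, loglik=-2.5, name="b")]
        tab = selection_table(models)
        assert tab["selected"].sum() == 1


class TestSurvivalTable:
    def test_logit_link_identity(self):
        rng = np.random.default_rng(23)
        hists = simulate_cjs(rng, n=150, T=3, phi={"adult_female": 0.5},
                             p={"female": 1.0})
        m = fit_cjs(CJSData(hists), SurvivalDesign((), ("sex",)))
        tab = monthly_survival_table(m)
        assert tab["phi_monthly"].iloc[0] == pytest.approx(
            float(expit(m.beta_phi[0])))

    def test_recovery_of_sex_specific_truth(self):
        rng = np.random.default_rng(29)
        hists = simulate_cjs(rng, n=600, T=3)
        m = fit_cjs(CJSData(hists), SurvivalDesign(("sexage",), ("sex",)))
        tab = monthly_survival_table(m)
        by = tab.groupby("sexage")["phi_monthly"].mean()
        assert by["adult_female"] == pytest.approx(0.46, abs=0.05)
        assert by["adult_male"] == pytest.approx(0.29, abs=0.05)

    def test_zero_recapture_year_boundary_flagged(self):
        rng = np.random.default_rng(31)
        good = simulate_cjs(rng, n=120, T=3, year=2010)
        dead = [AnnualHistory(f"z{k}", 2012, "wet", np.array([1, 0, 0]),
                              "adult_male", "wet") for k in range(9)]
        m = fit_cjs(CJSData(good + dead),
                    SurvivalDesign(("year",), ("sex",)))
        tab = monthly_survival_table(m)
        z = tab[tab["year"] == "2012"]
        assert (z["phi_monthly"] < 0.01).all()
        assert (z["flag"] == "boundary").all()


class TestDensityRegression:
    def test_flat_survival_slope_ci_contains_zero(self):
        import pandas as pd
        rng = np.random.default_rng(37)
        df = pd.DataFrame(dict(
            phi_monthly=np.clip(0.4 + rng.normal(0, 0.03, 30), 0.05, 0.95),
            se_phi=0.03,
            density_ha=np.exp(rng.uniform(np.log(0.05), np.log(9), 30)),
            se_density=0.1, grid=["wet"] * 30))
        res = survival_density_regression(df, B=400, seed=0, include_group=False)
        assert res.lo95[res.terms.index("density")] <= 0 <= res.hi95[res.terms.index("density")]

    def test_positive_dependence_sign_recovered(self):
        import pandas as pd
        rng = np.random.default_rng(41)
        hits = 0
        for rep in range(20):
            d = np.exp(rng.uniform(np.log(0.05), np.log(9), 40))
            phi = expit(logit(0.35) + 0.05 * d + rng.normal(0, 0.15, 40))
            df = pd.DataFrame(dict(phi_monthly=phi, se_phi=0.04, density_ha=d,
                                   se_density=0.05 * d, grid=["wet"] * 40))
            res = survival_density_regression(df, B=150, seed=rep,
                                              include_group=False)
            hits += res.coef("density") > 0
        assert hits >= 19  # sign recovered in >= 95% of replicates

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            survival_density_regression(pd.DataFrame())
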