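import numpy as np
import pytest

from cyclecmr.datamodel import TrapGrid, build_session_histories
from cyclecmr._numutil import expit, logit
from cyclecmr.secr import (
    _SessionData, build_mask, derive_density, esa_from_params,
    estimate_all_sessions, estimate_session, fit_conditional, halfnormal,
)

from conftest import simulate_session


class TestHalfnormal:
    def test_identity_at_zero(self):
        assert halfnormal(0.0, 0.3, 15.0) == pytest.approx(0.3)

    def test_closed_form_at_sigma(self):
        assert halfnormal(15.0, 0.3, 15.0) == pytest.approx(0.3 * np.exp(-0.5))

    def test_vanishes_far_away(self):
        assert halfnormal(1e6, 0.3, 15.0) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            halfnormal(1.0, 0.3, 0.0)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 200, 100)
        g = halfnormal(d, 0.25, 20.0)
        assert np.all(np.diff(g) < 0)


class TestMask:
    def test_extent_and_count(self, grid12):
        mask = build_mask(grid12, buffer_m=100.0, spacing_m=10.0)
        xs = mask.points[:, 0]
        # 330-m station extent + 2 x 100-m buffer = 530-m span
        assert xs.max() - xs.min() == pytest.approx(530.0)
        assert mask.n_points == 54 * 54  # verified by direct enumeration of the lattice

    def test_zero_buffer_is_bounding_box(self, grid12):
        mask = build_mask(grid12, buffer_m=0.0, spacing_m=30.0)
        assert mask.points[:, 0].min() == 0.0
        assert mask.points[:, 0].max() == pytest.approx(330.0)

    def test_doubling_spacing_quarters_count(self, grid12):
        n1 = build_mask(grid12, spacing_m=10.0).n_points
        n2 = build_mask(grid12, spacing_m=20.0).n_points
        assert n1 / n2 == pytest.approx(4.0, rel=0.15)

    def test_bad_spacing(self, grid12):
        with pytest.raises(ValueError):
            build_mask(grid12, spacing_m=0.0)


class TestConditionalFit:
    def test_matches_brute_force_grid_search(self, grid12, coarse_mask):
        """Optimiser must find the same maximum as a 25x25 parameter sweep."""
        rng = np.random.default_rng(2)
        events, _, _ = simulate_session(grid12, rng, density_ha=2.0)
        hs = build_session_histories(events, grid12, n_occasions=6)
        data = _SessionData(hs, grid12, coarse_mask)
        g0_grid = np.linspace(logit(0.05), logit(0.8), 25)
        sig_grid = np.linspace(np.log(5.0), np.log(60.0), 25)
        vals = np.array([[data.negloglik(np.array([a, b])) for b in sig_grid]
                         for a in g0_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        fit = fit_conditional(hs, grid12, coarse_mask)
        assert -fit.loglik <= vals[i, j] + 1e-6
        dg0 = g0_grid[1] - g0_grid[0]
        dsig = sig_grid[1] - sig_grid[0]
        assert abs(logit(fit.g0) - g0_grid[i]) <= dg0
        assert abs(np.log(fit.sigma_m) - sig_grid[j]) <= dsig

    def test_local_maximum(self, grid12, coarse_mask, small_session):
        hs, _, _ = small_session
        fit = fit_conditional(hs, grid12, coarse_mask)
        data = _SessionData(hs, grid12, coarse_mask)
        opt = np.array([logit(fit.g0), np.log(fit.sigma_m)])
        f0 = data.negloglik(opt)
        for d in [(0.05, 0), (-0.05, 0), (0, 0.05), (0, -0.05)]:
            assert data.negloglik(opt + np.array(d)) >= f0 - 1e-8

    def test_single_capture_flagged_nonidentifiable(self, grid12, coarse_mask):
        from cyclecmr.datamodel import CaptureEvent
        events = [CaptureEvent("a", 2010, 1, 1, "wet", 5, 5, "F", 30.0)]
        hs = build_session_histories(events, grid12, n_occasions=6)
        fit = fit_conditional(hs, grid12, coarse_mask)
        assert "non_identifiable" in fit.flags
        assert not fit.converged

    def test_no_detections_error(self, grid12, coarse_mask):
        with pytest.raises(ValueError):
            fit_conditional([], grid12, coarse_mask)


class TestDensity:
    def test_saturated_detection_limit(self, grid12, small_session):
        """With p(x) ~ 1 over the mask, density tends to n / mask area."""
        hs, _, _ = small_session
        mask = build_mask(grid12, buffer_m=100.0, spacing_m=15.0)
        from cyclecmr.secr import DetectionFit
        a = esa_from_params(grid12, mask, g0=0.999, sigma_m=5000.0, n_occasions=6)
        assert a == pytest.approx(mask.area_ha, rel=1e-3)
        fit = DetectionFit(g0=0.999, sigma_m=5000.0, loglik=0.0, esa_ha=a,
                           n_individuals=len(hs), n_occasions=6,
                           vcov_link=np.zeros((2, 2)))
        est = derive_density(fit, len(hs), mask)
        assert est.density == pytest.approx(len(hs) / mask.area_ha, rel=1e-3)

    def test_zero_detections_flagged(self, grid12, coarse_mask, small_session):
        hs, _, _ = small_session
        fit = fit_conditional(hs, grid12, coarse_mask)
        est = derive_density(fit, 0, coarse_mask)
        assert est.density == 0.0
        assert "no_detections" in est.flags

    def test_mask_refinement_invariance(self, grid12, small_session):
        """Halving mask spacing changes the density estimate by < 1%."""
        hs, _, _ = small_session
        d = {}
        for sp in (10.0, 5.0):
            mask = build_mask(grid12, 100.0, sp)
            fit = fit_conditional(hs, grid12, mask)
            d[sp] = derive_density(fit, len(hs), mask, grid=grid12).density
        assert abs(d[5.0] - d[10.0]) / d[10.0] < 0.01

    def test_buffer_extension_invariance(self, grid12, small_session):
        """Extending the buffer beyond 100 m changes density by < 2% (sigma ~ 15 m)."""
        hs, _, _ = small_session
        d = {}
        for buf in (100.0, 150.0):
            mask = build_mask(grid12, buf, 10.0)
            fit = fit_conditional(hs, grid12, mask)
            d[buf] = derive_density(fit, len(hs), mask, grid=grid12).density
        assert abs(d[150.0] - d[100.0]) / d[100.0] < 0.02


class TestSessionRouting:
    def test_low_abundance_pooled(self, grid12, coarse_mask):
        rng = np.random.default_rng(4)
        events, _, _ = simulate_session(grid12, rng, density_ha=0.15,
                                        classes=["adult_female", "adult_male"])
        hs = build_session_histories(events, grid12, n_occasions=6)
        assert 1 <= len(hs) <= 5
        ests = estimate_session(hs, grid12, coarse_mask)
        assert all(e.pooled for e in ests if e.n > 0)

    def test_high_abundance_separate(self, grid12, coarse_mask):
        rng = np.random.default_rng(5)
        events, _, _ = simulate_session(
            grid12, rng, density_ha=6.0,
            classes=["adult_female", "adult_male", "juvenile_female", "juvenile_male"])
        hs = build_session_histories(events, grid12, n_occasions=6)
        assert len(hs) > 20
        ests = estimate_session(hs, grid12, coarse_mask)
        assert any(not e.pooled for e in ests)
        # proportions of detected individuals per class should roughly match
        total = sum(e.density for e in ests)
        assert total > 0

    def test_batch_table_shape(self, grid12):
        rng = np.random.default_rng(6)
        events, _, _ = simulate_session(grid12, rng, density_ha=1.0,
                                        classes=["adult_female", "adult_male"])
        tab = estimate_all_sessions(events, [grid12], mask_spacing_m=15.0)
        assert set(tab["sexage"]) == {"adult_female", "adult_male",
                                      "juvenile_female", "juvenile_male"}
        assert (tab.groupby(["year", "primary", "grid_id"]).size() == 4).all()
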