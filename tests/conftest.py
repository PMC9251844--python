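import numpy as np
import pytest

from cyclecmr.datamodel import AnnualHistory, TrapGrid, build_session_histories
from cyclecmr.secr import build_mask
from cyclecmr.simulate import SimulationTruth, TrueIndividual, simulate_detections


@pytest.fixture(scope="session")
def grid12():
    return TrapGrid("wet", "wet", 12, 12)


@pytest.fixture(scope="session")
def coarse_mask(grid12):
    """15-m mask: fast enough for repeated fits, fine enough for sigma ~ 15 m."""
    return build_mask(grid12, buffer_m=100.0, spacing_m=15.0)


def simulate_session(grid, rng, density_ha=5.0, g0=0.3, sigma=15.0, n_occasions=6,
                     classes=None):
    """One closed-session dataset from known truth (uniform activity centres)."""
    truth = SimulationTruth(g0=g0, sigma_m=sigma)
    xy = grid.station_xy()
    lo = xy.min(axis=0) - 100.0
    hi = xy.max(axis=0) + 100.0
    area_ha = (hi[0] - lo[0]) * (hi[1] - lo[1]) / 1e4
    n = rng.poisson(density_ha * area_ha)
    inds = []
    for k in range(n):
        if classes is None:
            sex, age = "F", "adult"
        else:
            cls = classes[k % len(classes)]
            age, sexword = cls.split("_")
            sex = "F" if sexword == "female" else "M"
        mass = 40.0 if age == "adult" else 22.0
        inds.append(TrueIndividual(id=f"s{k:04d}", sex=sex, age=age,
                                   ac=(rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])),
                                   mass_g=mass))
    events = simulate_detections(inds, grid, n_occasions, truth, rng,
                                 sigma_override=sigma)
    return events, n, area_ha


def simulate_cjs(rng, n=400, T=3, phi=None, p=None, year=2010, grid_level="wet"):
    """Direct CJS data generator (independent of the SECR machinery)."""
    phi = phi or {"adult_female": 0.46, "adult_male": 0.29}
    p = p or {"female": 0.88, "male": 1.0}
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
        hists.append(AnnualHistory(f"i{i:04d}", year, "wet", pres, cls, grid_level))
    return hists


@pytest.fixture(scope="session")
def small_session(grid12):
    rng = np.random.default_rng(11)
    events, n_true, area = simulate_session(grid12, rng, density_ha=3.0)
    hs = build_session_histories(events, grid12, n_occasions=6)
    return hs, n_true, area
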