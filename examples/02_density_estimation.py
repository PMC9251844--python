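"""Estimate density for one trapping session with spatially explicit CMR.

Detection probability declines with distance from an animal's activity
centre as g(d) = g0 exp(-d^2 / 2 sigma^2); the conditional likelihood
estimates (g0, sigma), and density follows from the effective sampling area:
D-hat = n / a(theta-hat).
"""

import numpy as np

from cyclecmr import TrapGrid, build_mask, build_session_histories, derive_density, fit_conditional
from cyclecmr.simulate import SimulationTruth, TrueIndividual, simulate_detections

rng = np.random.default_rng(3)
grid = TrapGrid("wet", "wet", 12, 12)          # 144 traps, 30-m spacing
truth = SimulationTruth(g0=0.3, sigma_m=15.0)

# true population: 5 animals/ha on the grid plus a 100-m buffer
area_ha = (330 + 200) ** 2 / 1e4
n_true = rng.poisson(5.0 * area_ha)
animals = [TrueIndividual(f"a{k}", "F", "adult",
                          (rng.uniform(-100, 430), rng.uniform(-100, 430)), 40.0)
           for k in range(n_true)]
events = simulate_detections(animals, grid, 6, truth, rng, sigma_override=15.0)
histories = build_session_histories(events, grid, n_occasions=6)

mask = build_mask(grid, buffer_m=100.0, spacing_m=10.0)
fit = fit_conditional(histories, grid, mask)
est = derive_density(fit, len(histories), mask, grid=grid)

print(f"true density        : 5.00 animals/ha ({n_true} animals on {area_ha:.1f} ha)")
print(f"animals detected    : {len(histories)}")
print(f"g0-hat              : {fit.g0:.3f}   (truth 0.30; per-occasion capture prob at the centre)")
print(f"sigma-hat           : {fit.sigma_m:.1f} m (truth 15; half-normal movement scale)")
print(f"effective sampl.area: {fit.esa_ha:.2f} ha (mask integral of the detection prob)")
print(f"D-hat               : {est.density:.2f} /ha, 95% CI [{est.lo95:.2f}, {est.hi95:.2f}]")
print("\nThe CI combines detection-parameter uncertainty (delta method) with")
print("Poisson variation in the number of animals detected.")
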