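"""Generate a synthetic 16-year cyclic-population trapping study.

The generator emulates a robust-design live-trapping program: 3 grids,
3-4 primary periods per summer, 6 secondary occasions per primary, densities
cycling ~100-fold with a 4-year period, and sex/age/density-dependent
survival, movement and reproduction.  The paired truth record makes every
downstream estimate checkable.
"""

import pandas as pd

from cyclecmr import SimulationTruth, simulate_study

truth = SimulationTruth(seed=7)
events, record = simulate_study(truth)

df = pd.DataFrame([(e.year, e.primary, e.grid_id, e.individual_id) for e in events],
                  columns=["year", "primary", "grid", "id"])
real = pd.DataFrame(record["realized_sessions"])

print(f"capture events: {len(df)}, distinct individuals: {df['id'].nunique()}")
print("\ntrue June density (animals/ha) per year, wet grid:")
wet = real[(real.grid_id == "wet") & (real.primary == 1)]
print(wet.set_index("year")["density_ha"].round(2).to_string())
print("\nThe ~100-fold swing between trough (~0.05/ha) and peak (~9/ha) years")
print("with a 4-year period is the cyclic dynamic the analyses dissect.")
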