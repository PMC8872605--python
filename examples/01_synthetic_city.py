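"""Generate a synthetic city and look at its planted structure.

The generator builds everything the downstream analyses need: a grid of
traffic analysis zones (TAZ) with a spatially smooth population field,
hospitals placed preferentially in populous cells with resource attributes
correlated with local population, a lattice road network with shortest-path
origin-destination distances, and a yearly indicator panel ("yearbook").

Run with:  python examples/01_synthetic_city.py
"""

import numpy as np

from medcarry import (
    SyntheticCityConfig,
    YearbookConfig,
    generate_city,
    generate_od_matrix,
    generate_yearbook,
    hospital_supply_scores,
)

# A 20x20 km city with 67 public hospitals; supply level tracks population
# with a target correlation of 0.7, except in the NW quadrant where
# hospitals are deliberately under-resourced (a planted mismatch zone).
cfg = SyntheticCityConfig(
    grid_nx=20,
    grid_ny=20,
    n_hospitals=67,
    supply_demand_corr=0.7,
    mismatch_zones=[("NW", "under")],
    seed=42,
)
demand, hospitals, road = generate_city(cfg)

print(f"{len(demand)} demand zones, {len(hospitals)} hospitals")
print(f"population per zone: {demand['population'].min():.0f}"
      f" .. {demand['population'].max():.0f}")

# The composite supply score (entropy-weighted beds, personnel, grade)
# correlates with local population city-wide ...
scores = hospital_supply_scores(hospitals)
pop_at_hospital = demand.set_index(["row", "col"]).loc[
    list(zip(hospitals["row"], hospitals["col"])), "population"
].to_numpy()
r = np.corrcoef(scores, pop_at_hospital)[0, 1]
print(f"supply-population correlation: {r:.2f}")

# ... but the planted NW zone breaks the relation locally.
print("\nmean beds by quadrant:")
print(hospitals.groupby("quadrant")["beds"].mean().round(0).to_string())

# Travel distances come from shortest paths on the road lattice, not
# straight lines.
od = generate_od_matrix(demand, hospitals, road)
print(f"\nOD matrix: {od.values.shape[0]} x {od.values.shape[1]},"
      f" distances {od.values.min():.0f} .. {od.values.max():.0f} m")

# The yearbook panel drives the coordination analysis (example 03).
yearbook = generate_yearbook(YearbookConfig(), seed=42)
print(f"\nyearbook: {yearbook.shape[0]} years x {yearbook.shape[1]} indicators")
print(yearbook.iloc[-3:, :3].round(0).to_string())
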