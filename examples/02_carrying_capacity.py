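"""Carrying capacity of each demand zone via kernel-decay 2SFCA.

The two-step floating catchment area method asks, for every demand zone,
how much hospital supply is effectively reachable once every hospital's
resources have been shared among the population inside its catchment.
A kernel weight G(d) = 0.75 * (1 - (d/d0)^2) discounts distant
interactions; the catchment radius d0 is set so that every zone can reach
at least one hospital.

Run with:  python examples/02_carrying_capacity.py
"""

from medcarry import (
    SyntheticCityConfig,
    classify_capacity,
    compute_threshold,
    generate_city,
    generate_od_matrix,
    grade_summary,
    hospital_supply_scores,
    step1_ratios,
    step2_capacity,
)

demand, hospitals, road = generate_city(SyntheticCityConfig(seed=42))
od = generate_od_matrix(demand, hospitals, road)
scores = hospital_supply_scores(hospitals)

# The threshold is the largest nearest-hospital distance over all zones:
# the smallest radius at which nobody is left without a reachable hospital.
d0 = compute_threshold(od)
print(f"catchment threshold d0 = {d0:.0f} m")

# Step 1: each hospital's supply-to-weighted-demand ratio within d0.
ratios, unreached = step1_ratios(
    scores.to_numpy(), demand["population"].to_numpy(), od, d0
)
print(f"hospitals with no demand in range: {int(unreached.sum())}")

# Step 2: each zone sums the ratios of the hospitals it can reach.
capacity = step2_capacity(ratios, od, d0, mode="paper")

# Grade the capacity values into five classes by Jenks natural breaks and
# summarize counts and percentage shares per grade.
breaks, grades = classify_capacity(capacity, 5)
print()
print(grade_summary(grades, breaks=breaks).to_string(index=False))

# "symmetric" mode applies the kernel in step 2 as well; it conserves
# total supply exactly: sum_i population_i * A_i == sum_j score_j.
a_sym = step2_capacity(ratios, od, d0, mode="symmetric")
total = float(demand["population"].to_numpy() @ a_sym)
print(f"\nsymmetric mode conservation: {total:.6f}"
      f" == total supply {scores.sum():.6f}")
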