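"""Multicriteria synthesis: 0-100 scores and ranking of replacement foods.

Runs the full scenario matrix (every candidate alternative plus the animal
comparators, for meat and for dairy), min-max normalizes each domain within
its pool, and combines the subdomain scores with the weighting tree (health
/ environment / cost one third each; GHG 0.65, land 0.17, water 0.18 inside
environment). 100 = best in every domain within the pool.
"""

from dietswap import GeneratorSpec, generate_bundle
from dietswap.replacement import run_all
from dietswap.synthesis import WEIGHT_SCHEMES, rank_correlation, synthesize
from dietswap.synthetic_data import default_scenarios

bundle = default_scenarios(generate_bundle(GeneratorSpec(seed=0)))
changes = run_all(bundle)
scores = synthesize(changes)

for replace in ("meat", "dairy"):
    pool = scores[scores["replace"] == replace].sort_values("rank")
    print(f"\nreplacing {replace} (calorie basis):")
    for _, row in pool.iterrows():
        print(f"  #{int(row['rank']):>2} {row['alternative']:>15}: "
              f"{row['summary_score']:5.1f}/100")

# sensitivity: equal environmental subweights instead of planetary-boundary
alt_scores = synthesize(changes, WEIGHT_SCHEMES["equal_env"])
meat = scores[scores["replace"] == "meat"]
meat_alt = alt_scores[alt_scores["replace"] == "meat"]
rho = rank_correlation(
    dict(zip(meat["alternative"], meat["summary_score"])),
    dict(zip(meat_alt["alternative"], meat_alt["summary_score"])),
)
print(f"\nSpearman rank correlation main vs equal-env weights (meat pool): {rho:.3f}")
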