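"""Generate the synthetic voter population and inspect its calibration.

Builds the 50,000-person finite population (age ~ 82·Beta(2,3)+18, with
nationality, education, internet access and three vote indicators hanging
off it) and prints the realised conditional rates next to their target
probabilities, plus the three finite-population voting truths.
"""

from psadjust import (
    expected_internet_count,
    generate_population,
    true_proportion,
)

pop = generate_population(50_000, seed=1)

young = pop["age"] < 35
old = pop["age"] > 65
print(f"internet users: {pop.internet.sum()}  (analytic expectation "
      f"{expected_internet_count():.0f})")
print(f"P1 vote among females:   {pop.loc[pop.gender=='female','vote_p1'].mean():.3f}  (target 0.20)")
print(f"P2 vote among over-65s:  {pop.loc[old,'vote_p2'].mean():.3f}  (target 0.60)")
print(f"P3 vote, no internet:    {pop.loc[~pop.internet,'vote_p3'].mean():.3f}  (target 0.10)")
print(f"primary edu, over-65s:   {(pop.loc[old,'education']=='primary').mean():.3f}  (target 0.80)")
print(f"non-native, under-35s:   {(pop.loc[young,'nationality']=='non-native').mean():.3f}  (target 0.15)")

print("\nfinite-population truths (the targets PSA estimators chase):")
for party in ("p1", "p2", "p3"):
    overall = true_proportion(pop, party)
    online = true_proportion(pop, party, "internet")
    print(f"  {party}: overall {overall:.4f}   internet-only {online:.4f}   "
          f"gap {online-overall:+.4f}")
# The p3 gap (~ +0.115) is the selection bias an internet-only volunteer
# sample carries before any adjustment.
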