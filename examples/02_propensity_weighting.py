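"""One full PSA pass: draw samples, fit propensities, weight, estimate.

Draws a 500-person probability reference sample from the full population
and a 2,000-person volunteer sample from the internet subpopulation with
age-biased self-selection, fits logistic participation propensities on the
stacked dataset and compares unadjusted vs Hajek-weighted vs class-weighted
estimates of the Party 2 voting proportion with the population truth.
"""

from psadjust import (
    clip_propensities,
    combine,
    draw_convenience,
    fit_propensity,
    generate_population,
    hajek_weights,
    ht_class_weights,
    internet_population,
    srswor,
    stratify_by_propensity,
    true_proportion,
    weighted_proportion,
    PropensitySpec,
)

pop = generate_population(50_000, seed=1)
reference = srswor(pop, 500, seed=10)
volunteer = draw_convenience(internet_population(pop), "logit_linear", 2000, seed=11)
sample = combine(reference, volunteer, ["age", "gender", "nationality", "education"])

model, raw = fit_propensity(sample, PropensitySpec("logistic"))
clipped = clip_propensities(raw)
vol = sample.volunteer_mask()

hajek = hajek_weights(clipped.values[vol])
classes = stratify_by_propensity(sample, raw, n_classes=5)
ht = ht_class_weights(sample, classes)

y = sample.extra.loc[vol, "vote_p2"].to_numpy(dtype=float)
truth = true_proportion(pop, "p2")
print(f"population truth (Party 2):        {truth:.4f}")
print(f"unadjusted volunteer estimate:     {y.mean():.4f}   error {y.mean()-truth:+.4f}")
est_hajek = weighted_proportion(y, hajek)
print(f"PSA, Hajek inverse-odds weights:   {est_hajek:.4f}   error {est_hajek-truth:+.4f}")
est_ht = weighted_proportion(y, ht)
print(f"PSA, 5-class HT-type weights:      {est_ht:.4f}   error {est_ht-truth:+.4f}")
# Both weighted estimates should sit much closer to the truth: the volunteer
# pool skews young and online, and Party 2 support rises with age.
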