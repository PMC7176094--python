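"""Cross-validated hyperparameter tuning by propensity log-loss.

Grid-searches the k-NN neighbour count on one combined sample using
repeated stratified 10-fold cross-validation (scaled down to 3 repeats) of
the out-of-fold log-loss of the membership indicator z.
"""

from psadjust import (
    combine,
    draw_convenience,
    expand_grid,
    generate_population,
    internet_population,
    srswor,
    tune_cv,
)

pop = generate_population(20_000, seed=2)
reference = srswor(pop, 300, seed=20)
volunteer = draw_convenience(internet_population(pop), "logit_linear", 600, seed=21)
sample = combine(reference, volunteer, ["age", "gender", "nationality", "education"])

grid = expand_grid("knn")  # k in {3, 5, 7, 9, 11, 13}
result = tune_cv(sample, grid, folds=10, repeats=3, seed=0)
print(result.losses.to_string(index=False))
print(f"\nselected: k = {result.best.hyperparameters['k']} "
      f"(mean CV log-loss {result.best_loss:.4f})")
# Lower log-loss means the estimated propensities track actual volunteer
# participation more faithfully; larger k smooths the local vote fractions.
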