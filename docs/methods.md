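# Methods

## The adjustment procedure

Let U be a finite population, U_v ⊂ U the subpopulation reachable by an
online volunteer survey, s_v a self-selected sample of size n_vs from U_v
(base weights d_j = 1) and s_r a probability sample of size n_rs from U
with design weights d_k = 1/π_k (N/n_rs under simple random sampling
without replacement). The target variable y is observed only on s_v;
covariates x are observed on both. On the stacked sample of size
n = n_vs + n_rs, z marks volunteer membership, and π(x) = P(z = 1 | x) is
estimated by a classification model. Two reweightings of s_v follow:

* **Propensity classes (Horvitz–Thompson type).** Units are sorted by π̂
  and cut into C classes at the C-quantiles of the combined π̂
  distribution (C = 5 by default, the usual stratification choice).
  Within class c the volunteer base weights are multiplied by the ratio
  of reference-to-volunteer weight shares f_c. The construction
  telescopes, so Σ w over volunteers equals Σ d over volunteers exactly;
  the test suite checks this to 1e-10.
* **Inverse odds (Hajek type).** w_j = (1 − π̂_j)/π̂_j. These weights
  adjust s_v toward the population represented by the reference sample.
  Because count-based estimators (trees, forests, k-NN at small k) emit
  exact 0s and 1s, raw propensities are pushed into the open interval by
  x ↦ (1000x + 0.5)/1001 before inversion; the map is monotone, fixes
  0.5, and is applied automatically whenever a boundary value appears.

Estimates are always the normalised ratio Σwy/Σw, for both schemes. This
keeps every estimated proportion inside [min y, max y] and removes the
scale ambiguity of unnormalised inverse-odds totals. The simulation
engine defaults to Hajek weighting; class weighting is selectable
everywhere.

All propensity models are fitted unweighted: base design weights enter
only the class-adjustment factor f_c, never the classification fit.

## Propensity estimators

All estimators consume a one-hot encoded covariate matrix (categorical
levels sorted and frozen at encoding time; age left numeric), except
Naive Bayes, which reads the raw covariate frame — treating the dummies
of one categorical as independent features would double-count it. The
combined sample carries both representations.

* **Logistic** — unpenalised maximum likelihood (scikit-learn lbfgs,
  tolerance 1e-10). The score equation makes the mean in-sample π̂ equal
  n_vs/n to numerical precision. Quasi-separation is detected by
  coefficient magnitude (|β| > 15) or a hit iteration cap and reported
  as a warning while still returning the capped fit.
* **Single tree** — CART-style growth (entropy or Gini impurity, minimum
  node size as a fraction of n: 0.5%, 1% or 5%), then an error-based
  pessimistic pruning pass in the C4.5 tradition: each node's predicted
  error is n·U_CF(e, n) with U_CF the Clopper–Pearson upper confidence
  bound of the majority-class error rate at level 1 − CF
  (CF ∈ {0.1, 0.25, 0.5}; smaller CF prunes harder), and a subtree is
  collapsed when the collapsed node's predicted error does not exceed
  the sum over its leaves. π̂ is the volunteer fraction of the effective
  terminal node, counted on the training sample. One tree learner with
  both impurities stands in for the C4.5/C5.0/CART trio; rule sets,
  winnowing and boosting trials are not reimplemented, as the two
  entropy-based variants behave nearly identically in this role.
* **Random forest** — bootstrap trees on mtry-subsampled covariates
  (500 trees by default). π̂ is the fraction of trees whose terminal node
  is majority-volunteer (leaf volunteer fraction ≥ 0.5 counts as a
  volunteer vote), i.e. a vote fraction, not the average of leaf
  fractions. With m trees π̂ takes values in {0, 1/m, …, 1}.
* **k-NN** — Euclidean distance on the encoded matrix with numeric
  columns min-max scaled to [0,1] and dummies unscaled. π̂ is the
  volunteer fraction among the k nearest *other* units (the unit itself
  is excluded when scoring in-sample); distance ties at the k-th
  neighbour are broken by lowest row index so exactly k neighbours
  count, which keeps π̂ ≤ 1 under heavy ties. When scoring units outside
  the training sample (cross-validation), the k nearest training units
  are used without exclusion.
* **Naive Bayes** — P(z=1|x) ∝ P(z=1)·Π P(x_m|z=1) with add-λ
  (λ ∈ {0, 1, 2, 5, 10}) smoothing of categorical conditionals over the
  levels observed in the combined sample, and per-class Gaussian
  densities for numeric covariates (smoothing applies to categorical
  conditionals only). With λ = 0 an unseen level zeroes a class
  likelihood; if both class likelihoods vanish the prior is returned.
* **GBM** — stagewise gradient boosting of depth-limited regression
  trees (interaction depth ∈ {4, 6, 8}, learning rate ∈ {0.1, 0.01,
  0.001}) minimising the Bernoulli deviance, with 100 trees and 50% row
  subsampling per stage by default; π̂ is the logistic transform of the
  additive score. `n_trees=0` returns the intercept-only (base-rate)
  model. Training deviance is non-increasing when subsampling is
  disabled; with subsampling it is so only in expectation.

A note on degenerate no-information inputs (identical covariate rows,
balanced classes): logistic, tree and Naive Bayes return exactly 0.5
everywhere; GBM lands within a few hundredths of it; the forest's
majority-vote indicator is a step function at 0.5, so only bootstrap
averaging brings it near the base rate; and k-NN's answer depends on the
row-index tie-break, so no base-rate identity holds for it.

## The synthetic voter population

The generator emulates a national electorate with an internet-access
divide: N individuals (50,000 by default) with

* age = 82x + 18, x ~ Beta(2, 3), kept continuous; the age strata <35,
  35–65 (both ends inclusive), >65 are derived. Their analytic masses
  from the Beta CDF are 0.192 / 0.596 / 0.211;
* non-native shares 15% / 10% / 2.5% by stratum; gender 50/50
  independent of everything (this is what makes Party 1 MCAR);
* education primary/secondary/higher at 35/20/45, 45/25/30, 80/10/10 by
  stratum;
* internet access 90/70/50% for natives and 20/10/0% for non-natives by
  stratum (expected online subpopulation ≈ 31,877 of 50,000);
* votes: Party 1 = Bernoulli(0.20) for women, never for men (MCAR);
  Party 2 = Bernoulli(0 / 0.40 / 0.60) by stratum (MAR through age);
  Party 3 = Bernoulli(0.10) offline, Bernoulli(0.60 / 0.40 / 0.20) by
  stratum online (NMAR: the outcome depends on the selection variable).

The three vote indicators are drawn independently per person — the three
party proportions are estimated separately and no mutual exclusivity is
imposed, so "votes" are really three separate intention questions.
Analytically, the overall truths are p1 = 0.100, p2 = 0.365, p3 = 0.301,
with an internet-only Party-3 proportion of 0.416: an internet-only
sample overstates Party 3 by ≈ +0.115 before adjustment. Population
truths used by the evaluation engine are, however, the *empirical*
fractions of the generated table, so Bias and MSE are exact for the
realised finite population.

What the generator does not emulate: measurement error, item and unit
nonresponse within the samples, correlated vote choices, household
clustering, or covariate measurement differences between the two
samples. Passing Monte-Carlo tests therefore demonstrates correctness of
the adjustment machinery under a clean selection model, not performance
on real panel data.

## Sampling schemes

The reference sample is SRSWOR from the full population (weights N/n_rs).
The volunteer sample of fixed size n_vs is drawn from the internet
subpopulation either uniformly or with age-driven self-selection
probabilities π = 1/(1+e^(−1+0.05·age)) (decreasing in age) or
π = 1/(1+e^(1−sin(age/20))) (oscillating). Fixed-size unequal-probability
draws use exponential sampling keys E_i/π_i (smallest n_vs kept), which
realises sequential without-replacement sampling with probability
proportional to π among the remaining units — one concrete mechanism for
"unequal self-selection at fixed sample size"; with all π equal it
reduces exactly to SRSWOR.

## Monte-Carlo evaluation

A scenario fixes scheme, n_vs (500–10,000), n_rs (500), estimators and
weighting; the population is generated once and held fixed across
replications, mirroring a design in which one finite population is the
estimand. Each replication redraws both samples, fits every estimator on
the same draw (a paired design that removes between-sample noise from
algorithm contrasts), weights, and estimates each party's proportion
alongside the unadjusted volunteer mean. Default replication count is
500; tests and examples scale this down (200 replications at n_vs = 2000
for the headline MCAR/MAR/NMAR checks, 3–40 elsewhere) to keep runs in
the seconds-to-minutes range. All randomness descends from one master
seed through named spawned streams (population, per-replication draws,
per-(replication, estimator) fits), so results are bit-reproducible.

When a simulated bias is compared against an *analytic* superpopulation
value (Party 1's zero, Party 3's +0.115 gap), the tolerance is
3·sqrt(SE_mc² + SE_pop²), where SE_mc is the Monte-Carlo standard error
of the mean estimate and SE_pop the analytic standard error of the
realised domain gap in one population draw. At 200 replications the two
terms are the same order of magnitude (≈ 5–8×10⁻⁴ vs ≈ 1–1.7×10⁻³), so
ignoring the population-draw term would reject a correct implementation
on a sizeable fraction of seeds.

Hyperparameter tuning minimises the out-of-fold log-loss
−(1/n)Σ[z log π̂ + (1−z) log(1−π̂)] (π̂ clipped at 10⁻¹⁵) over repeated
stratified 10-fold cross-validation, folds shared across grid points;
ties go to grid order.

## Numerical choices and edge cases

* Propensity-class boundaries are right-closed with ties kept in the
  lower class; tied quantiles collapse classes with a warning. A class
  lacking volunteer units or reference weight is merged with its
  neighbour toward the centre class (warned); how such classes should be
  handled is genuinely open, and merging inward preserves the mass
  identity.
* A constant π̂ makes both weighting schemes return the unadjusted
  volunteer proportion exactly.
* `mse` uses the M−1 divisor for the variance term, so MSE = variance +
  bias² is an identity the suite verifies to 1e-12.
* Zero total weight, single-class z, empty domains, out-of-range
  propensities and oversized draws raise typed exceptions
  (`psadjust.exceptions`).

## Known limitations

* Only single-stage reference designs are honoured; stratified or
  clustered reference samples would need their weights collapsed to
  per-unit d_k first.
* No analytic variance estimation for the weighted estimators — only
  replication-based Bias/MSE.
* The pessimistic-pruning pass approximates the C4.5 family; exact C5.0
  rule sets, winnowing and boosted trials are out of scope, as are
  calibration/raking on top of PSA, matching estimators and neural-net
  propensities.
* Internet-access realisations are binomial around their expectation;
  any single population draw differs from the analytic subpopulation
  size by ~±110 individuals (1 SD).
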