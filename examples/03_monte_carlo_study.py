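"""Replicated bias/MSE comparison of PSA estimators.

Runs a scaled-down scenario study (40 replications) comparing logistic and
gradient-boosting propensities under age-biased self-selection, reporting
bias and MSE for each party next to the unadjusted volunteer estimate.
"""

from psadjust import PropensitySpec, ScenarioConfig, run_scenario

config = ScenarioConfig(
    scheme="logit_linear",
    n_vs=1000,
    n_rs=500,
    reps=40,
    estimators=[
        PropensitySpec("logistic"),
        PropensitySpec("gbm", {"interaction_depth": 6, "learning_rate": 0.1}),
    ],
    weighting="hajek",
    master_seed=123,
)
result = run_scenario(config)
cols = ["estimator", "party", "bias", "mse", "unadjusted_bias", "unadjusted_mse"]
print(result.summary()[cols].to_string(index=False, float_format=lambda v: f"{v:+.5f}"))
# Party 1 (MCAR) is unbiased even unadjusted; Party 2 (MAR) bias shrinks
# sharply under PSA; Party 3 (NMAR) bias is reduced but not removed, since
# selection depends on the outcome itself through internet access.
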