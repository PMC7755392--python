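"""Model comparison: additive vs multiplicative value integration.

Simulates choices from the additive model (#2), fits both the additive and
the multiplicative expected-value model (#1), and ranks them by PSIS-LOO.
The generating model should win by more than two standard errors of the
difference.
"""

import warnings

import volatility_learner as vl
from volatility_learner.compare import compare

warnings.filterwarnings("ignore")

truth = vl.simulate_cohort(
    vl.CohortSpec(n_subjects=20, task_versions=("gain",),
                  population=vl.default_population(vl.get_model_spec("m2")),
                  seed=3)
)

lls = {}
for mid in ("m1", "m2"):
    spec = vl.get_model_spec(mid)
    model = vl.build_model(spec, truth.datasets, truth.scores)
    res = vl.fit(model, chains=2, tune=300, draws=400, seed=1)
    lls[mid] = res.pointwise_loglik(max_draws=400)

table = compare(lls)
print(table.round(1).to_string())
# 'deviance' is -2 * elpd (lower is better); 'elpd_diff' is each model's
# expected log predictive density relative to the best model, with the
# standard error of that difference ('se_diff') from the pointwise spread.
diff = table.iloc[1]
print(f"\npreferred: {table.index[0]}  "
      f"(difference {diff['elpd_diff']:.1f} +- {diff['se_diff']:.1f})")
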