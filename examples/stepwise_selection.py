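"""How many excess bells does the data support?

A series with exactly two bells is simulated; the model is then refined
stepwise from zero to three bells.  Each row reports the weighted deviance,
residual degrees of freedom, overdispersion and the scaled F-test for the
added term: the first two additions are overwhelmingly significant, the
third (fitting noise) is not.
"""

import mortrend as mt
from mortrend.models import ModelSpec, ParameterSet

truth_spec = ModelSpec(family="logistic", n_excess=2)
truth = ParameterSet(alpha=0.003, beta1=-1.5, beta2=-0.07,
                     excess=[(5.0, 3.45, 0.13), (15.0, 3.85, 0.11)])
config = mt.SimConfig(1950, 2018, truth, truth_spec,
                      births_per_year=2_000_000, seed=11)
series = mt.simulate_series(config)

fits, comparisons = mt.stepwise_fit(series, ModelSpec(family="logistic", n_excess=3), 3)
print(mt.comparison_table(fits, comparisons).to_string(index=False))
print("\nstop adding bells once the scaled F-test stops rejecting (p > 0.05)")
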