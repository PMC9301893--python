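"""Estimate v-ratio (and the other five parameters) for one simulated subject.

Simulate a subject with known parameters, apply the standard RT exclusions,
then fit the six-parameter model (drift v, boundary a, non-decision time Ter,
v-ratio, confidence mapping M and SD) by quantile optimization with
differential evolution. With the budget used here a fit takes on the order of
a minute on one CPU; increase the budget for production fits.
"""

import numpy as np

from vratio import (
    DDMParams,
    FitConfig,
    apply_exclusions,
    fit_ddm,
    generate_confidence_rt_pool,
    simulate_dataset,
)
from vratio.confidence import ConfidenceScaleSpec

rng = np.random.default_rng(11)
scale = ConfidenceScaleSpec.six_point()

true = DDMParams(drift_v=2.0, boundary_a=1.5, ter=0.4, v_ratio=0.7,
                 conf_M=2.5, conf_SD=1.2)
pool = generate_confidence_rt_pool(true, 1000, rng)
dataset = simulate_dataset(true, 500, pool, rng, scale_spec=scale)
dataset, report = apply_exclusions(dataset)
print("exclusions:", report)

config = FitConfig(n_sim=5000, population=60, max_generations=60,
                   stall_generations=30, seed=1)
result = fit_ddm(dataset, scale, config)

print(f"objective {result.objective_value:.4f} after {result.n_evaluations} evaluations")
names = ["drift_v", "boundary_a", "ter", "v_ratio", "conf_M", "conf_SD"]
est = [result.drifts[0], result.params.boundary_a, result.params.ter,
       result.v_ratio, result.params.conf_M, result.params.conf_SD]
for name, t, e in zip(names, [true.drift_v, true.boundary_a, true.ter,
                              true.v_ratio, true.conf_M, true.conf_SD], est):
    print(f"{name:>11}  true {t:5.2f}  estimated {e:5.2f}")
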