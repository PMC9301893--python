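"""Simulate one observer and compute the static metacognition metrics.

The observer decides via a drift diffusion process and keeps accumulating
evidence after the choice (for as long as their confidence RT) with drift
scaled by v-ratio. We then score their confidence with the classic static
measures: d', meta-d', M-ratio and type-II AUC.
"""

import numpy as np

from vratio import (
    DDMParams,
    generate_confidence_rt_pool,
    simulate_dataset,
    type2_auc,
)
from vratio.confidence import ConfidenceScaleSpec
from vratio.metrics import bin_confidence, build_sdt_table, fit_meta_d

rng = np.random.default_rng(7)

# a moderately cautious observer with imperfect post-decisional accumulation
params = DDMParams(drift_v=2.0, boundary_a=1.5, ter=0.35, v_ratio=0.8,
                   conf_M=2.5, conf_SD=1.2)

# post-decision accumulation lasts as long as a confidence RT drawn from this pool
pool = generate_confidence_rt_pool(params, 1000, rng)

dataset = simulate_dataset(params, 1000, pool, rng,
                           scale_spec=ConfidenceScaleSpec.six_point())

print(f"accuracy        {dataset.accuracy.mean():.3f}")
print(f"mean RT         {dataset.rt.mean():.3f} s")
print(f"mean confidence {dataset.confidence.mean():.2f} (1-6 scale)")

labels = bin_confidence(dataset.confidence, 4)
table = build_sdt_table(dataset.trials["stimulus"], dataset.trials["choice"], labels, 4)
md = fit_meta_d(table)
auc = type2_auc(dataset.accuracy, dataset.confidence)

print(f"d'              {md.d_prime:.3f}")
print(f"meta-d'         {md.meta_d_prime:.3f}")
print(f"M-ratio         {md.m_ratio:.3f}")
print(f"type-II AUC     {auc:.3f}")
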