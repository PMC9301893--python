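# vratio

Dynamic measures of metacognitive accuracy from a drift diffusion model with
post-decisional evidence accumulation.

Static measures of metacognition such as M-ratio (meta-d′/d′) treat confidence
as a snapshot. But confidence judgments, like the decisions before them, unfold
in time: evidence keeps accumulating after the choice, and how faithfully it
does so is a *dynamic* property of the observer. This package implements that
dynamic framework:

- **Simulator** — a two-boundary drift diffusion process (random-walk
  approximation, step τ = 0.001 s) whose evidence continues to accumulate,
  unbounded, after the boundary crossing for the duration of the trial's
  confidence RT. The post-decision drift is `v · v-ratio`; **v-ratio** is the
  dynamic measure of metacognitive accuracy (1 = post-decision evidence as
  informative as decision evidence, 0 = pure noise).
- **Confidence mapping** — raw confidence `(evidence + M) / SD`, discretized to
  a rating scale (or clamped, with a "center pull" toward the scale midpoint
  for continuous scales).
- **Static metrics** — d′, maximum-likelihood meta-d′ (with an unequal-variance
  option), M-ratio, and type-II ROC AUC, for comparison.
- **Fitting** — the six parameters (v, a, Ter, v-ratio, M, SD; per-condition
  drifts on request) estimated per subject by quantile optimization: a
  chi-square distance between observed and simulated proportions in
  accuracy-conditioned RT and confidence bins, minimized by differential
  evolution over a deterministic common-random-numbers objective.
- **Study harnesses** — the 100-agent simulation study showing that M-ratio is
  confounded with response caution (decision boundary) while v-ratio is not,
  and a simulate-then-refit parameter-recovery harness.
- **IO + CLI** — validated trial-table reading/writing, the standard RT
  exclusions, and a `vratio` command-line interface.

## Quick start

```python
import numpy as np
from vratio import (DDMParams, generate_confidence_rt_pool, simulate_dataset,
                    type2_auc)
from vratio.confidence import ConfidenceScaleSpec
from vratio.metrics import bin_confidence, build_sdt_table, fit_meta_d

rng = np.random.default_rng(7)
params = DDMParams(drift_v=2.0, boundary_a=1.5, ter=0.35, v_ratio=0.8,
                   conf_M=2.5, conf_SD=1.2)
pool = generate_confidence_rt_pool(params, 1000, rng)
ds = simulate_dataset(params, 1000, pool, rng,
                      scale_spec=ConfidenceScaleSpec.six_point())

labels = bin_confidence(ds.confidence, 4)
md = fit_meta_d(build_sdt_table(ds.trials["stimulus"], ds.trials["choice"], labels, 4))
print(md.d_prime, md.meta_d_prime, md.m_ratio)
```

Output (examples/01_simulate_and_measure.py):

```
accuracy        0.959
mean RT         0.703 s
mean confidence 3.72 (1-6 scale)
d'              3.476
meta-d'         1.697
M-ratio         0.488
type-II AUC     0.746
```

Fitting a subject (see `examples/02_fit_single_subject.py`):

```python
from vratio import FitConfig, apply_exclusions, fit_ddm

ds, report = apply_exclusions(ds)          # rt < 100 ms, confidence RT > 5 s
res = fit_ddm(ds, ConfidenceScaleSpec.six_point(),
              FitConfig(n_sim=5000, population=60, max_generations=60,
                        stall_generations=30, seed=1))
print(res.v_ratio, res.params)
```

## Command line

```bash
vratio simulate --drift 2 --boundary 1.5 --v-ratio 0.8 --n-trials 1000 \
       --seed 1 --out trials.csv
vratio metrics trials.csv --bins 4 --out metrics.csv
vratio fit trials.csv --config fit.yaml --seed 1 --out fit.csv
vratio repro-sim --n-agents 100 --n-trials 1000 --seed 1 --out agents.csv
vratio recover --n-subjects 10 --n-trials 1000 --seed 1 --out recovery.csv
```

Every command writes a JSON run manifest (seed, settings, exclusion counts)
beside its output.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` checks every acceptance criterion at its stated
tolerance (the recovery tests take several minutes each); the other modules
carry fast unit and property-based tests against closed-form oracles.

## Layout

- `src/vratio/` — `ddm` (simulator + analytic oracles), `confidence`
  (Eq.-6 mapping, discretization, center pull), `metrics` (d′/meta-d′/M-ratio/
  type-II AUC), `fitting` (quantile chi-square + differential evolution),
  `study` (simulation study and recovery harness), `io` (trial tables,
  exclusions), `cli`.
- `examples/` — narrative scripts 01–04.
- `docs/methods.md` — model definition, numerical choices, known limitations.
- `scripts/acceptance.py` — reproducibility report (JSON).
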