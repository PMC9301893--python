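"""Small parameter-recovery check: simulate from known parameters, refit.

Five subjects at 1000 trials each with a compact differential-evolution budget
(a few minutes on one CPU). For a serious recovery study raise n_subjects,
n_trials and the DE budget; identifiability at a few hundred trials is weak for
subjects whose accuracy saturates (see docs/methods.md).
"""

from vratio import FitConfig, run_recovery

config = FitConfig(n_sim=4000, population=60, max_generations=60,
                   stall_generations=30)
result = run_recovery(n_subjects=5, n_trials=1000, fit_config=config, seed=3)

print(f"failed fits: {result.n_failed}")
for name, r in result.correlations.items():
    print(f"recovery r({name}) = {r:+.3f}")

print("\ntrue vs recovered:")
joined = result.true_params.add_prefix("true_").join(
    result.recovered_params.add_prefix("est_")
)
print(joined.round(2).to_string())
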