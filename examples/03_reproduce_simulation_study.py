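"""Reproduce the simulation study: M-ratio is confounded with response caution.

100 agents x 1000 trials, parameters drawn from the documented uniform ranges.
The headline result: M-ratio (the static measure of metacognitive efficiency)
correlates positively with the generative v-ratio but *negatively* with the
decision boundary, even though v-ratio and boundary are independent by
construction. Takes a minute or so on one CPU.
"""

from vratio import SimStudyConfig, run_simulation_study

result = run_simulation_study(SimStudyConfig(n_agents=100, n_trials=1000, seed=1))

print("pairwise Pearson correlations (selected):")
for a, b in [
    ("m_ratio", "v_ratio"),
    ("m_ratio", "boundary_a"),
    ("v_ratio", "boundary_a"),
    ("d_prime", "boundary_a"),
    ("meta_d_prime", "boundary_a"),
    ("drift_v", "m_ratio"),
    ("mean_rt", "mean_conf_rt"),
    ("mean_conf_rt", "boundary_a"),
]:
    r = result.corr(a, b)
    p = float(result.p_values.loc[a, b])
    print(f"  {a:>13} ~ {b:<13} r = {r:+.3f}  (p = {p:.4f})")

print(f"\nagents with undefined metrics: {result.n_failed}")
print("full correlation matrix:")
print(result.correlations.round(3).to_string())
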