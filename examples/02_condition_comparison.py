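"""Compare network metrics between a control and a hyperconnected field.

Runs the full pipeline (simulate -> normalize -> correlate -> gate ->
graph metrics) for both conditions and reports the node-level normalized
degree comparison: shared ensemble events in the hyperconnected condition
raise each neuron's count of significant functional connections.
"""

import synconnect as sc

cfgs = {
    "control": sc.make_config("control", seed=1, n_neurons=20),
    "hyperconnected": sc.make_config("hyperconnected", seed=2, n_neurons=20),
}
res = sc.run_pipeline(cfgs, alpha=0.05)

print(res.summary_table().to_string(index=False))
c = res.comparison
print(f"\nnormalized degree, control {c.mean_a:.3f} ± {c.sem_a:.3f} vs "
      f"hyperconnected {c.mean_b:.3f} ± {c.sem_b:.3f}")
print(f"two-sample t = {c.statistic:.2f}, p = {c.p_value:.2e} "
      f"({c.direction}; node-level n = {c.n_a}/{c.n_b})")
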