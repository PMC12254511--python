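"""Single-neuron electrophysiology: firing rate, AP half-width, ramp
capacitance, and hyperpolarization resilience.

Simulates stylized patch-clamp sweeps with known ground truth and shows
each estimator recovering it: the capacitance estimate should match the
simulated 100 pF cell regardless of leak, and the impaired neuron's
percent change in firing should be strongly negative.
"""

import synconnect as sc

# spontaneous firing and AP half-width
sw = sc.simulate_sweep("spontaneous", seed=3, rate=2.5, duration=30.0,
                       ap_half_width_ms=1.5)
spikes = sc.detect_spikes(sw)
hw = sc.half_width(sw, spikes[0])
print(f"firing rate {spikes.size / 30.0:.2f} Hz (simulated 2.5 Hz), "
      f"AP half-width {hw:.2f} ms (template 1.50 ms)")

# membrane capacitance from the -70 -> -80 -> -70 mV ramp
for rm in (100.0, 1000.0, float("inf")):
    ramp = sc.simulate_sweep("capacitance_ramp", cm_pf=100.0, rm_mohm=rm)
    est = sc.estimate_capacitance(ramp)
    print(f"Rm = {rm:>6} MOhm -> Cm = {est.cm_pf:.2f} pF (true 100 pF)")

# hyperpolarization challenge: intact vs impaired recovery
for label, mult in (("intact", 1.0), ("impaired", 0.4)):
    ch = sc.simulate_sweep("hyperpolarization_challenge", seed=9, rate=2.0,
                           recovery_multiplier=mult)
    st = sc.challenge_resilience(ch)
    print(f"{label}: {st.f_pre:.2f} Hz baseline -> {st.f_post:.2f} Hz "
          f"recovery, change {st.percent_change:+.1f}%")
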