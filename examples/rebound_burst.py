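"""Rebound burst firing driven by a recovered T-type current.

Inserts a synthetic T-type kinetic set into the baseline spiker, runs the
standard protocol (settle at +3 uA/cm^2, hyperpolarize to -5 uA/cm^2 for
70 ms, release), and prints the burst metrics next to the no-CaT control.
"""

from tburst import default_neuron, make_synthetic_cat, with_cat
from tburst.experiments import run_rebound_experiment

baseline = default_neuron()
cat = make_synthetic_cat("fast_recovery")

for name, params in (("no CaT (control)", baseline),
                     ("fast-recovery CaT", with_cat(baseline, cat))):
    res = run_rebound_experiment(params)
    m = res.metrics
    print(f"{name}:")
    print(f"  steady rate      {m.steady_frequency:7.1f} spikes/s")
    print(f"  rebound peak     {m.peak_frequency:7.1f} spikes/s "
          f"(ratio {m.rebound_ratio:.2f})")
    print(f"  time to peak     {m.time_to_peak:7.1f} ms after release")
    print(f"  decay to +/-10%  {m.decay_time:7.1f} ms after the peak")

print()
print("Without the T-type current the rate simply resumes its tonic value")
print("(ratio ~1).  With a fast-recovering T-type current the 70 ms")
print("hyperpolarization de-inactivates the channel and release fires a")
print("burst several times faster than the tonic rhythm, which then decays")
print("as the current inactivates.")
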