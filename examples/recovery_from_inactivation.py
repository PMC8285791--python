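"""Recovery from inactivation limits how much current a pause can recruit.

Computes the closed-form recovered fraction h(d) after hyperpolarizing holds
of graded length, for a fast- and a slow-recovering synthetic channel, and
shows the matching rebound peaks from full simulations.
"""

from tburst import default_neuron, make_synthetic_cat, recovery_fraction, with_cat
from tburst.experiments import run_rebound_experiment

baseline = default_neuron()
durations = [10.0, 35.0, 70.0, 140.0, 280.0]

for label in ("fast_recovery", "slow_recovery"):
    cat = make_synthetic_cat(label)
    h = recovery_fraction(cat, -90.0, durations)
    print(f"{label} (recovery tau at -90 mV ~ "
          f"{cat.inactivation.tau_hyper:.0f} ms):")
    for d, hh in zip(durations, h):
        marker = "  <- standard 70 ms step" if d == 70.0 else ""
        print(f"  hold {d:5.0f} ms -> h = {hh:.3f}{marker}")
    m = run_rebound_experiment(with_cat(baseline, cat)).metrics
    print(f"  rebound peak after the 70 ms step: {m.peak_frequency:.1f} spikes/s")

print()
print("The slow-recovering channel regains only a fraction of its")
print("availability during the 70 ms hyperpolarization, so its rebound burst")
print("is far weaker than the fast-recovering channel's.")
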