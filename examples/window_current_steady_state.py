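"""Window current and tonic firing.

The overlap of the activation and inactivation curves (the "window") lets a
small T-type current flow at steady state.  A large window shifts the tonic
firing rate; a negligible window leaves it untouched even though the same
channel still produces a rebound burst.
"""

import numpy as np

from tburst import default_neuron, make_synthetic_cat, window_profile, with_cat
from tburst.experiments import run_steady_state_experiment

baseline = default_neuron()
grid = np.linspace(-120.0, 0.0, 1201)

for label in ("large_window", "small_window"):
    cat = make_synthetic_cat(label)
    prof = window_profile(cat.activation, cat.inactivation, grid)
    res = run_steady_state_experiment(with_cat(baseline, cat))
    print(f"{label}:")
    print(f"  window peak {prof.peak:.2e} at {prof.peak_voltage:.1f} mV "
          f"(area {prof.area:.3f} mV)")
    print(f"  tonic rate  {res.frequency_with_cat:6.1f} Hz with CaT vs "
          f"{res.frequency_without_cat:6.1f} Hz without "
          f"({res.delta_percent:+.2f}%)")

print()
print("The steady-state contribution tracks the window overlap: the large-")
print("window variant shifts the tonic rate substantially while the small-")
print("window variant (peak < 1e-3) changes it by well under 2%.")
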