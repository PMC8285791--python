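# Methods

## Scope and intent

`tburst` is a reduced, single-compartment, Hodgkin–Huxley-style spiking model
with one optional low-threshold T-type calcium conductance.  It is a
*lever-isolation* tool: every mechanism through which a T-type variant can
shape firing — activation and inactivation kinetics, recovery from
inactivation, steady-state window current, and a temperature rescaling of
conductance and kinetics — is an explicit parameter, and the shipped
synthetic profiles each move exactly one of those levers.  It is not a model
of any particular neuron type, and it makes no claim about measured Cav3
kinetics: real values are meant to be transcribed into the YAML schema by
the user (the shipped six-slot template is flagged invalid until then).

## Gate model

All gates use a Boltzmann steady state and a sigmoidal blend between two
limiting time constants (see README for the equations).  This functional
form is a deliberate reconstruction choice, not a fit: it is the simplest
shape that expresses the three distinct time scales the science requires —
fast inactivation when depolarized, slow recovery when hyperpolarized, and a
smooth voltage dependence in between — with each limit an independent,
reviewable parameter.  The voltage-dependent τ lives entirely inside
`GateSpec`, so replacing the blend with another form (e.g. a bell-shaped τ)
is a one-module change in `gating.py`; nothing downstream inspects the shape.

The T-type current uses the m²h convention (activation squared, linear
inactivation); the exponent is a config field since conventions differ.
The driving force is ohmic, `ḡ m² h (V − E_CaT)` with `E_CaT = +120 mV`,
rather than a Goldman–Hodgkin–Katz flux: the ohmic form keeps the current
contract analytic and the conductance parameter directly interpretable.
Swapping in GHK permeation would be confined to `model.i_cat` and the
compiled channel evaluation in `simulate`.

## Baseline spiker

The Na/K/leak backbone (`tburst/data/default_neuron.yaml`) is an engineering
baseline tuned to four requirements, in order of importance:

1. tonic, stationary firing at the +3 μA/cm² holding current of the standard
   protocol (≈ 40 spikes/s), quiescent at and below ≈ 2.6 μA/cm², monotone
   f–I up to ≈ 10 μA/cm²;
2. release from the −5 μA/cm² step returns the rate to its tonic value with
   no overshoot (rebound ratio ≈ 1 without a T-type current), so every burst
   in the experiments is attributable to the inserted current;
3. an interspike voltage trajectory spanning ≈ −71…−50 mV and a
   hyperpolarized level of ≈ −75 mV during the −5 μA/cm² step, so a
   low-threshold window placed near −50/−75 mV is functionally engaged and
   the step genuinely de-inactivates it;
4. no time constant faster than 0.2 ms, so the default 0.02 ms step resolves
   every gate (this bounds the integrator's splitting error; see below).

Na activation is near-instantaneous (τ = 0.2 ms) and the parameters carry no
temperature dependence by design — the model isolates the consequences of
*channel* temperature sensitivity, holding the spike generator fixed.

## Integration

Fixed-step integration only: protocols contain current discontinuities, and
aligning segment boundaries to grid points (durations must be multiples of
dt) keeps every discontinuity between steps.  Two methods:

- `exponential-euler`: symmetric (Strang) splitting — analytic gate
  relaxation for dt/2 at the current voltage, an exact solve of the linear
  voltage equation for dt with conductances frozen at their mid-step values,
  then analytic gate relaxation for dt/2 at the new voltage.  Both sub-flows
  are exact, so the scheme is exact under voltage clamp and for the
  zero-conductance charge balance, and second-order accurate in the
  voltage–gate coupling.  A plain sequential (first-order) variant was
  rejected because its phase error accumulates to ~1 ms of spike-time drift
  over a one-second run at dt = 0.01 ms, an order of magnitude worse than
  the package's own cross-check bounds.
- `rk4`: classical Runge–Kutta on the full coupled system, used as the
  independent numerical cross-check.

Gates are clipped to [0, 1] only as a guard; excursions beyond 1e−9 are
counted on the trace and logged, and the test suite requires zero events on
healthy runs.  A non-finite voltage aborts with the failure time.  There is
no randomness anywhere in the simulator; identical inputs give bit-identical
trajectories, which is what makes the byte-identical CLI reproducibility
guarantee possible.

## Protocols and analysis

The standard rebound protocol settles the model at +3 μA/cm² (stationarity =
coefficient of variation of the last 10 interspike intervals < 0.01), holds
that rhythm for 200 ms, steps to −5 μA/cm² for 70 ms, and returns for
500 ms.  The pre-step hold at the post-step level reflects the protocol's
intent — the hyperpolarization interrupts an established rhythm — and is
overridable.  The 500 ms post window is 2.5× the slowest decay any shipped
variant exhibits (~200 ms) while keeping runs compact.

Spikes are upward crossings of −20 mV with linear interpolation between
samples and a 2 ms refractory window; both are config-exposed, as the
detection convention is not part of the science.  Instantaneous frequency is
1000/ISI assigned to the *second* spike of each interval — the simplest
convention for plotting frequency against time since release.  Rebound
metrics: peak = maximum instantaneous frequency at or after release (ties →
earliest); time-to-peak is measured from release; decay time is measured
from the peak to the first frequency point back inside a ±10% (relative,
config-exposed) band around the pre-step steady rate, zero if the peak is
already in band, NaN if the window ends first.  With no post-release spikes
the metrics are flagged undefined rather than invented.

## Synthetic profiles and the temperature transform

The fixture anchors (activation −50/6 mV, inactivation −75/6 mV, ḡ = 0.7
mS/cm²) place the window current inside the baseline's interspike voltage
range at a conductance that drives clear bursts while staying below the
depolarization-block regime under the default temperature transform; they
are engineering choices, not measurements.  Each profile overrides exactly
one base field:

| profile | field | value | property pinned |
|---|---|---|---|
| fast_recovery | inact. τ_hyper | 18 ms | recovery ≪ 70 ms step (≤ 70/3 even at max jitter) |
| slow_recovery | inact. τ_hyper | 280 ms | recovery ≫ step (≥ 3×70 even at max jitter) |
| fast_inactivation | inact. τ_depol | 15 ms | short burst |
| slow_inactivation | inact. τ_depol | 60 ms | long burst |
| large_window | inact. V½ | −72 mV | sizeable steady-state overlap |
| small_window | inact. V½ | −110 mV | window peak < 1e−3 |

Seeded multiplicative jitter (≤ 20%, NumPy `default_rng`, bit-stable across
platforms) perturbs the non-defining fields; the defining field is re-pinned
after jittering so each profile's property holds exactly.

The temperature transform multiplies ḡ by `g_scale ≥ 1` (default 2) and all
four limiting time constants of both gates by `tau_scale ≤ 1` (default 1/3),
leaving midpoints, slopes — and therefore the window profile — untouched.
The defaults encode only the *direction* of warming from room to
physiological temperature; they are parameters, not measured Q10s.

## What the synthetic data does and does not show

The profiles let every qualitative mechanism be exercised without any
transcribed literature kinetics: recovery speed sets the rebound peak,
inactivation speed sets the decay, window size sets the steady-state shift,
and warming raises/sharpens the burst.  Passing tests therefore demonstrate
that the *model machinery* expresses each mechanism with the correct sign
and a clean control — not that any real Cav3 isoform behaves quantitatively
like a profile.  Known regime limits, found by exploration and deliberately
avoided by the defaults: conductances ≳ 2 mS/cm² combined with a large
window drive the spiker into depolarization block during the burst, and the
peak-frequency gain under warming can invert when recovery is already
complete at the cold condition and the tonic drive is weak (the ±5% jittered
variants of `fast_recovery` sit near that boundary).  Real neurons with
calcium-activated or adaptation currents would blunt both effects; no such
currents are modeled.

## Numerical cross-check bounds

The suite holds the integrator to: gate trajectories within 1e−6 of the
closed form under clamp (dt = 0.01 ms); paired-pulse recovery within 1e−3 of
the analytic fraction; exponential-euler vs rk4 spike times within 0.2 ms
and dt-halving shifts under 0.1 ms on the standard fast-recovery rebound run
(measured ≈ 0.03 ms and ≈ 0.08 ms respectively); and exact charge balance
for the pure capacitor.

## Known limitations

Single compartment; no calcium concentration dynamics or calcium-activated
currents; ohmic rather than GHK permeation; no stochastic gating, noise or
synaptic input; a monotone (not bell-shaped) τ(V); temperature enters only
through the two-factor transform of the T-type parameters, never the Na/K
backbone.  Mixed-isoform co-expression is out of scope: one `CaTParams`
slot per model.
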