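"""Synthetic T-type kinetic sets with controlled, named properties.

Real Cav3.1/3.2/3.3 kinetics must be transcribed from published voltage-clamp
measurements into the parameter schema; the generators here instead produce
*synthetic* kinetic sets in which exactly one mechanistic lever is pinned to a
known value, so every qualitative claim about rebound bursting can be tested
without any literature numbers:

``fast_recovery`` / ``slow_recovery``
    Recovery-from-inactivation time constant well below / well above the
    70 ms hyperpolarizing step of the standard rebound protocol (a
    Cav3.1-like vs Cav3.2-like contrast).
``fast_inactivation`` / ``slow_inactivation``
    Inactivation time constant at depolarized voltages (sets burst duration).
``large_window`` / ``small_window``
    Overlap of the activation and inactivation curves (steady-state window
    current), moved by shifting the inactivation midpoint only.
``custom``
    The unmodified base set.

All anchor values (midpoints near -50/-75 mV, slopes ~6 mV) are engineering
choices placing the window near the baseline model's interspike voltage range
so the current is functionally engaged; they are not measurements.  A
seeded multiplicative jitter perturbs every kinetic field while preserving
each profile's defining property, and a simple two-factor temperature
transform (conductance up, every time constant down) emulates the direction
of warming from room to physiological temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gating import (
    ACTIVATION,
    INACTIVATION,
    GateSpec,
    relax_gate_closed_form,
    steady_state,
    time_constant,
)
from .model import CaTParams

__all__ = [
    "PROFILE_LABELS",
    "KineticProfile",
    "make_synthetic_cat",
    "temperature_transform",
    "recovery_fraction",
]

# Standard rebound protocol hyperpolarization length (ms); recovery profiles
# are pinned to >= 3x / <= 1/3 of it, with margin for the maximum 20% jitter.
STEP_DURATION = 70.0

_BASE_ACTIVATION = GateSpec(
    v_half=-50.0,
    slope=6.0,
    polarity=ACTIVATION,
    tau_depol=1.5,
    tau_hyper=6.0,
    tau_v_mid=-45.0,
    tau_slope=8.0,
    exponent=2,
)
_BASE_INACTIVATION = GateSpec(
    v_half=-75.0,
    slope=6.0,
    polarity=INACTIVATION,
    tau_depol=25.0,
    tau_hyper=60.0,
    tau_v_mid=-70.0,
    tau_slope=6.0,
    exponent=1,
)
_BASE_G_MAX = 0.7  # mS/cm^2
_BASE_E_REV = 120.0  # mV, ohmic stand-in for the calcium reversal

# each profile overrides exactly one field of the base set
_PROFILE_OVERRIDES: dict[str, dict[str, dict[str, float]]] = {
    "custom": {},
    "fast_recovery": {"inactivation": {"tau_hyper": 18.0}},
    "slow_recovery": {"inactivation": {"tau_hyper": 280.0}},
    "fast_inactivation": {"inactivation": {"tau_depol": 15.0}},
    "slow_inactivation": {"inactivation": {"tau_depol": 60.0}},
    "large_window": {"inactivation": {"v_half": -72.0}},
    "small_window": {"inactivation": {"v_half": -110.0}},
}

PROFILE_LABELS = tuple(_PROFILE_OVERRIDES)

_JITTER_FIELDS = ("v_half", "slope", "tau_depol", "tau_hyper", "tau_v_mid", "tau_slope")


@dataclass(frozen=True)
class KineticProfile:
    """Deterministic recipe (label, seed, jitter) for one synthetic CaT set."""

    label: str
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in _PROFILE_OVERRIDES:
            raise ValueError(
                f"unknown profile label {self.label!r}; known: {PROFILE_LABELS}"
            )
        if not (0.0 <= self.jitter <= 0.2):
            raise ValueError(f"jitter must lie in [0, 0.2], got {self.jitter}")


def _jittered_gate(spec: GateSpec, rng: np.random.Generator, jitter: float) -> GateSpec:
    if jitter == 0.0:
        return spec
    changes = {}
    for name in _JITTER_FIELDS:
        u = rng.uniform(-1.0, 1.0)
        changes[name] = getattr(spec, name) * (1.0 + jitter * u)
    return replace(spec, **changes)


def make_synthetic_cat(profile: KineticProfile | str, seed: int = 0, jitter: float = 0.0) -> CaTParams:
    """Generate the CaT parameter set for a kinetic profile.

    Accepts either a :class:`KineticProfile` or a bare label (with ``seed``
    and ``jitter`` as keywords).  The mapping (label, seed, jitter) ->
    parameters is deterministic and bit-stable across runs.
    """
    if isinstance(profile, str):
        profile = KineticProfile(label=profile, seed=seed, jitter=jitter)
    overrides = _PROFILE_OVERRIDES[profile.label]
    act = replace(_BASE_ACTIVATION, **overrides.get("activation", {}))
    inact = replace(_BASE_INACTIVATION, **overrides.get("inactivation", {}))
    g_max = _BASE_G_MAX
    if profile.jitter > 0.0:
        rng = np.random.default_rng(profile.seed)
        act = _jittered_gate(act, rng, profile.jitter)
        inact = _jittered_gate(inact, rng, profile.jitter)
        # the profile's defining field stays pinned so the named property is
        # preserved exactly under jitter
        for gate_name, fields in overrides.items():
            if gate_name == "inactivation":
                inact = replace(inact, **fields)
            else:
                act = replace(act, **fields)
        g_max = g_max * (1.0 + profile.jitter * rng.uniform(-1.0, 1.0))
    return CaTParams(
        isoform_label=f"syn-{profile.label}",
        temperature_label="21C",
        g_max=g_max,
        e_rev=_BASE_E_REV,
        activation=act,
        inactivation=inact,
    )


def _scale_taus(spec: GateSpec, tau_scale: float) -> GateSpec:
    return replace(
        spec,
        tau_depol=spec.tau_depol * tau_scale,
        tau_hyper=spec.tau_hyper * tau_scale,
    )


def temperature_transform(
    cat: CaTParams,
    g_scale: float = 2.0,
    tau_scale: float = 1.0 / 3.0,
    temperature_label: str = "37C",
) -> CaTParams:
    """Warm a kinetic set: conductance up, every time constant down.

    Multiplies ``g_max`` by ``g_scale`` (>= 1) and all four limiting time
    constants of both gates by ``tau_scale`` (in (0, 1]); Boltzmann midpoints
    and slopes — hence the window profile — are untouched.  The default
    scales (2, 1/3) encode only the *direction* of the change from room to
    physiological temperature, not any measured Q10.
    """
    if not (np.isfinite(g_scale) and g_scale >= 1.0):
        raise ValueError(f"g_scale must be >= 1, got {g_scale}")
    if not (np.isfinite(tau_scale) and 0.0 < tau_scale <= 1.0):
        raise ValueError(f"tau_scale must lie in (0, 1], got {tau_scale}")
    return replace(
        cat,
        g_max=cat.g_max * g_scale,
        activation=_scale_taus(cat.activation, tau_scale),
        inactivation=_scale_taus(cat.inactivation, tau_scale),
        temperature_label=temperature_label,
    )


def recovery_fraction(cat: CaTParams, v_hold: float, durations) -> np.ndarray:
    """Closed-form recovery from full inactivation at a holding voltage.

    Starting from h = 0 (fully inactivated), the available fraction after a
    hyperpolarizing hold of length d is
    ``h(d) = h_inf(v_hold) * (1 - exp(-d / tau_h(v_hold)))``.  Serves both as
    an analysis convenience and as the oracle for simulated paired-pulse
    recovery.  Returns a scalar for scalar input.
    """
    durations_arr = np.asarray(durations, dtype=float)
    if np.any(durations_arr < 0) or not np.all(np.isfinite(durations_arr)):
        raise ValueError("durations must be finite and non-negative")
    out = relax_gate_closed_form(cat.inactivation, v_hold, 0.0, durations_arr)
    return out if np.ndim(durations) else float(out)


def window_engagement_voltages(cat: CaTParams) -> tuple[float, float]:
    """Convenience: voltage range (mV) over which the window is non-trivial."""
    lo = min(cat.activation.v_half, cat.inactivation.v_half) - 30.0
    hi = max(cat.activation.v_half, cat.inactivation.v_half) + 30.0
    return lo, hi
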