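"""Hodgkin–Huxley-style gate kinetics.

Every voltage-gated conductance in the model is built from first-order gating
variables x(t) that relax toward a Boltzmann steady state x_inf(V) with a
voltage-dependent time constant tau_x(V):

    dx/dt = (x_inf(V) - x) / tau_x(V)

The steady state is a two-parameter Boltzmann curve (midpoint ``v_half``,
slope factor ``slope``), increasing with voltage for activation gates and
decreasing for inactivation gates.  The time constant is a smooth sigmoidal
blend between two limiting values: ``tau_depol`` at depolarized potentials and
``tau_hyper`` at hyperpolarized potentials.  For an inactivation gate
``tau_depol`` is the inactivation time constant (how fast the channel shuts
during a burst) and ``tau_hyper`` is the recovery-from-inactivation time
constant (how fast availability returns during a hyperpolarization) — a single
gate therefore carries both time scales, switched by voltage.

The closed-form relaxation at fixed voltage doubles as the analytic oracle for
the numerical integrator, and the product of the activation and inactivation
steady states gives the window-current profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ACTIVATION",
    "INACTIVATION",
    "GateSpec",
    "WindowProfile",
    "steady_state",
    "time_constant",
    "relax_gate_closed_form",
    "window_profile",
]

ACTIVATION = "activation"
INACTIVATION = "inactivation"


@dataclass(frozen=True)
class GateSpec:
    """Complete kinetic description of one gating variable.

    Parameters
    ----------
    v_half : float
        Boltzmann midpoint of the steady-state curve (mV).
    slope : float
        Boltzmann slope factor (mV, strictly positive); the sign of the
        voltage dependence is carried by ``polarity``, not by the slope.
    polarity : {"activation", "inactivation"}
        Whether the steady state increases or decreases with voltage.
    tau_depol, tau_hyper : float
        Limiting time constants (ms, > 0) at depolarized and hyperpolarized
        voltages respectively.  For an inactivation gate ``tau_hyper`` is the
        recovery-from-inactivation time constant.
    tau_v_mid, tau_slope : float
        Midpoint (mV) and slope (mV, > 0) of the sigmoidal blend between the
        two limiting time constants.
    exponent : int
        Power to which the gate is raised in the current equation (m^p h).
    """

    v_half: float
    slope: float
    polarity: str
    tau_depol: float
    tau_hyper: float
    tau_v_mid: float
    tau_slope: float
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in (ACTIVATION, INACTIVATION):
            raise ValueError(
                f"polarity must be {ACTIVATION!r} or {INACTIVATION!r}, "
                f"got {self.polarity!r}"
            )
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"slope must be a positive finite number, got {self.slope}")
        for name in ("tau_depol", "tau_hyper", "tau_slope"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be a positive finite number, got {val}")
        for name in ("v_half", "tau_v_mid"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (isinstance(self.exponent, (int, np.integer)) and self.exponent >= 1):
            raise ValueError(f"exponent must be a positive integer, got {self.exponent}")


def _as_voltage(v):
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage must be finite")
    return arr


def _maybe_scalar(out, v):
    if np.ndim(v) == 0:
        return float(out)
    return out


def steady_state(gate: GateSpec, v):
    """Boltzmann steady state x_inf(V), bounded in [0, 1].

    ``1/(1 + exp(-(V - v_half)/slope))`` for activation polarity and
    ``1/(1 + exp((V - v_half)/slope))`` for inactivation polarity.
    Accepts a scalar or array voltage (mV).
    """
    arr = _as_voltage(v)
    sign = 1.0 if gate.polarity == ACTIVATION else -1.0
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-sign * (arr - gate.v_half) / gate.slope))
    return _maybe_scalar(out, v)


def time_constant(gate: GateSpec, v):
    """Voltage-dependent relaxation time constant tau_x(V) in ms.

    Sigmoidal blend ``tau_hyper + (tau_depol - tau_hyper) * s(V)`` with
    ``s(V) = 1/(1 + exp(-(V - tau_v_mid)/tau_slope))``; strictly between the
    two limiting values at every finite voltage.
    """
    arr = _as_voltage(v)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-(arr - gate.tau_v_mid) / gate.tau_slope))
    out = gate.tau_hyper + (gate.tau_depol - gate.tau_hyper) * s
    return _maybe_scalar(out, v)


def relax_gate_closed_form(gate: GateSpec, v, x0: float, t):
    """Exact first-order relaxation at clamped voltage.

    ``x(t) = x_inf + (x0 - x_inf) * exp(-t / tau(V))`` — the analytic solution
    of the gate ODE at fixed V, used as the oracle for the numerical
    integrator.  ``t`` may be a scalar or array of times (ms, >= 0).
    """
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0 must lie in [0, 1], got {x0}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite and non-negative")
    x_inf = steady_state(gate, v)
    tau = time_constant(gate, v)
    out = x_inf + (x0 - x_inf) * np.exp(-t_arr / tau)
    return _maybe_scalar(out, t)


@dataclass(frozen=True)
class WindowProfile:
    """Steady-state open fraction m_inf^p * h_inf over a voltage grid."""

    voltages: np.ndarray
    open_fraction: np.ndarray
    peak: float
    peak_voltage: float
    area: float  # trapezoidal integral of the open fraction over the grid (mV)


def window_profile(act: GateSpec, inact: GateSpec, v_grid) -> WindowProfile:
    """Window-current profile from the overlap of activation and inactivation.

    The per-voltage open fraction is ``steady_state(act, V)**act.exponent *
    steady_state(inact, V)``; its peak locates the window current that can
    flow at steady state and its trapezoidal area summarizes the overlap.
    Ties on equal peak values resolve to the lowest voltage.
    """
    grid = _as_voltage(v_grid)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("v_grid must be one-dimensional with at least 3 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("v_grid must be strictly increasing")
    w = steady_state(act, grid) ** act.exponent * steady_state(inact, grid)
    idx = int(np.argmax(w))
    return WindowProfile(
        voltages=grid,
        open_fraction=w,
        peak=float(w[idx]),
        peak_voltage=float(grid[idx]),
        area=float(np.trapezoid(w, grid)),
    )
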