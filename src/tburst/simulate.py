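"""Deterministic fixed-step integration of the neuron model.

Protocols are ordered lists of constant-current (or voltage-clamp) segments;
segment boundaries are aligned exactly to the integration grid so that current
discontinuities never fall inside a step.  Two integration methods are
provided:

``exponential-euler``
    Symmetric operator splitting: each step relaxes every gate analytically
    toward its steady state for half a step, advances the voltage exactly for
    a full step treating the conductances as frozen (the voltage equation is
    then linear), and relaxes the gates for the second half step.  At clamped
    voltage the gate update is the exact closed form, and with all
    conductances zero the charge balance dV = i_app * dt / c_m holds to
    machine precision.

``rk4``
    Classical fourth-order Runge-Kutta on the full coupled system.

There is no randomness anywhere in the simulator: identical inputs produce
bit-identical trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import ACTIVATION
from .model import NeuronParams, gate_specs, state_names, steady_state_vector

__all__ = [
    "Segment",
    "Protocol",
    "Trace",
    "IntegrationError",
    "integrate",
    "settle_to_rhythm",
    "SettleResult",
]

logger = logging.getLogger(__name__)

METHODS = ("exponential-euler", "rk4")

# gates are clipped to [0, 1] as a guard; excursions beyond this are counted
# and logged (they must not occur in a correct run)
_CLAMP_TOL = 1e-9


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Segment:
    """One protocol step: constant applied current (uA/cm^2) for a duration.

    If ``v_clamp`` is set the membrane potential is held at that value for the
    whole segment (gates keep evolving); ``i_app`` is then ignored.
    """

    i_app: float
    duration: float
    v_clamp: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if not np.isfinite(self.i_app):
            raise ValueError("segment i_app must be finite")


@dataclass(frozen=True)
class Protocol:
    """Ordered current-step protocol with integration settings.

    ``init`` selects the initial state: ``"steady"`` (every gate at its
    steady state for ``v_init``), ``"settle"`` (run :func:`settle_to_rhythm`
    at the first segment's current and start from the settled state — the
    default for rebound runs, where tonic firing is established before the
    hyperpolarizing step), or an explicit state vector.
    """

    segments: tuple[Segment, ...]
    dt: float = 0.02
    sample_interval: float | None = None  # defaults to dt
    init: str | np.ndarray = "steady"
    v_init: float = -65.0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        if not (np.isfinite(self.dt) and 0 < self.dt <= 0.05):
            raise ValueError(f"dt must lie in (0, 0.05] ms, got {self.dt}")
        si = self.sample_interval
        if si is not None:
            ratio = si / self.dt
            if not math.isclose(ratio, round(ratio), rel_tol=0, abs_tol=1e-9):
                raise ValueError("sample_interval must be an integer multiple of dt")
        if isinstance(self.init, str) and self.init not in ("steady", "settle"):
            raise ValueError(f"unknown init mode {self.init!r}")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> np.ndarray:
        return np.cumsum([s.duration for s in self.segments])


@dataclass
class Trace:
    """Uniformly sampled trajectory of one integration run."""

    t: np.ndarray
    v: np.ndarray
    gates: dict[str, np.ndarray]
    i_cat: np.ndarray  # uA/cm^2, zero-filled when no CaT is present
    i_app: np.ndarray
    segment_boundaries: np.ndarray
    dt: float
    sample_interval: float
    n_clamp_events: int = 0
    method: str = "exponential-euler"

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_ms": self.t, "v_mv": self.v}
        for name, arr in self.gates.items():
            cols[name] = arr
        cols["i_cat_ua_cm2"] = self.i_cat
        cols["i_app_ua_cm2"] = self.i_app
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _compile(params: NeuronParams):
    """Flatten params into plain-float tuples for the scalar inner loops."""
    specs = gate_specs(params)
    gates = []
    for _, s in specs:
        sign = 1.0 if s.polarity == ACTIVATION else -1.0
        gates.append(
            (sign, s.v_half, s.slope, s.tau_hyper, s.tau_depol - s.tau_hyper,
             s.tau_v_mid, s.tau_slope)
        )
    channels = []
    idx = 0
    name_to_chan = {}
    for chan_name, chan in params.channels():
        powers = []
        for _, spec in chan.gates:
            powers.append((idx, int(spec.exponent)))
            idx += 1
        entry = (chan.g_max, chan.e_rev, tuple(powers))
        name_to_chan[chan_name] = entry
        channels.append(entry)
    cat_entry = name_to_chan.get("cat")
    return tuple(gates), tuple(channels), cat_entry, params.c_m


def _gate_targets(gates, v):
    """Per-gate (x_inf, tau) at voltage v."""
    out = []
    for sign, v_half, slope, tau_h, tau_diff, tau_mid, tau_slope in gates:
        a = -sign * (v - v_half) / slope
        if a > 700.0:
            x_inf = 0.0
        else:
            x_inf = 1.0 / (1.0 + math.exp(a))
        b = -(v - tau_mid) / tau_slope
        if b > 700.0:
            s = 0.0
        else:
            s = 1.0 / (1.0 + math.exp(b))
        out.append((x_inf, tau_h + tau_diff * s))
    return out


def _relax(gates, x, v, dt):
    """Analytic gate relaxation for one (sub-)step at frozen voltage."""
    for i, (x_inf, tau) in enumerate(_gate_targets(gates, v)):
        x[i] = x_inf + (x[i] - x_inf) * math.exp(-dt / tau)


def _membrane(channels, x, v):
    """(total conductance, total g*E drive, ionic current) at this state."""
    g_tot = 0.0
    ge_tot = 0.0
    i_ion = 0.0
    for g_max, e_rev, powers in channels:
        open_frac = 1.0
        for gi, p in powers:
            xi = x[gi]
            if p == 1:
                open_frac *= xi
            elif p == 2:
                open_frac *= xi * xi
            elif p == 3:
                open_frac *= xi * xi * xi
            elif p == 4:
                xi2 = xi * xi
                open_frac *= xi2 * xi2
            else:
                open_frac *= xi ** p
        g = g_max * open_frac
        g_tot += g
        ge_tot += g * e_rev
        i_ion += g * (v - e_rev)
    return g_tot, ge_tot, i_ion


def _i_cat_of(cat_entry, x, v):
    if cat_entry is None:
        return 0.0
    g_max, e_rev, powers = cat_entry
    open_frac = 1.0
    for gi, p in powers:
        open_frac *= x[gi] ** p
    return g_max * open_frac * (v - e_rev)


def _guard_gates(x, counter):
    for i, xi in enumerate(x):
        if xi < 0.0:
            if xi < -_CLAMP_TOL:
                counter[0] += 1
            x[i] = 0.0
        elif xi > 1.0:
            if xi > 1.0 + _CLAMP_TOL:
                counter[0] += 1
            x[i] = 1.0


def _step_expeuler(gates, channels, c_m, v, x, i_app, dt, v_clamp):
    if v_clamp is not None:
        _relax(gates, x, v_clamp, 0.5 * dt)
        _relax(gates, x, v_clamp, 0.5 * dt)
        return v_clamp
    _relax(gates, x, v, 0.5 * dt)
    g_tot, ge_tot, _ = _membrane(channels, x, v)
    a = g_tot * dt / c_m
    if a < 1e-12:
        # zero-conductance limit: pure capacitor, exact charge balance
        v_new = v + (i_app + ge_tot) * dt / c_m
    else:
        v_inf = (i_app + ge_tot) / g_tot
        v_new = v_inf + (v - v_inf) * math.exp(-a)
    _relax(gates, x, v_new, 0.5 * dt)
    return v_new


def _step_rk4(gates, channels, c_m, v, x, i_app, dt, v_clamp):
    n = len(x)

    def deriv(vv, xx):
        targets = _gate_targets(gates, vv)
        dx = [(t[0] - xx[i]) / t[1] for i, t in enumerate(targets)]
        if v_clamp is not None:
            dv = 0.0
        else:
            _, _, i_ion = _membrane(channels, xx, vv)
            dv = (i_app - i_ion) / c_m
        return dv, dx

    if v_clamp is not None:
        v = v_clamp
    dv1, dx1 = deriv(v, x)
    x2 = [x[i] + 0.5 * dt * dx1[i] for i in range(n)]
    dv2, dx2 = deriv(v + 0.5 * dt * dv1, x2)
    x3 = [x[i] + 0.5 * dt * dx2[i] for i in range(n)]
    dv3, dx3 = deriv(v + 0.5 * dt * dv2, x3)
    x4 = [x[i] + dt * dx3[i] for i in range(n)]
    dv4, dx4 = deriv(v + dt * dv3, x4)
    v_new = v + dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
    for i in range(n):
        x[i] += dt / 6.0 * (dx1[i] + 2.0 * dx2[i] + 2.0 * dx3[i] + dx4[i])
    if v_clamp is not None:
        return v_clamp
    return v_new


def _initial_state(params: NeuronParams, protocol: Protocol) -> np.ndarray:
    if isinstance(protocol.init, np.ndarray):
        state = np.asarray(protocol.init, dtype=float)
        n = 1 + len(gate_specs(params))
        if state.shape != (n,):
            raise ValueError(f"explicit init state must have shape ({n},)")
        return state.copy()
    if protocol.init == "steady":
        first = protocol.segments[0]
        v0 = first.v_clamp if first.v_clamp is not None else protocol.v_init
        return steady_state_vector(params, v0)
    # "settle": establish the tonic rhythm at the first segment's current
    first = protocol.segments[0]
    if first.v_clamp is not None:
        raise ValueError('init="settle" is not defined for a voltage-clamp segment')
    result = settle_to_rhythm(params, first.i_app, dt=protocol.dt)
    return result.state


def integrate(
    params: NeuronParams,
    protocol: Protocol,
    method: str = "exponential-euler",
) -> Trace:
    """Run a protocol and return the sampled trace.

    Deterministic: identical inputs give bit-identical output.  Gate values
    are clipped to [0, 1] only as a guard; genuine excursions are counted in
    ``Trace.n_clamp_events`` and logged (a correct run has zero).  A
    non-finite voltage aborts with :class:`IntegrationError` naming the time.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    step = _step_expeuler if method == "exponential-euler" else _step_rk4
    gates_c, channels_c, cat_entry, c_m = _compile(params)

    state0 = _initial_state(params, protocol)
    v = float(state0[0])
    x = [float(xi) for xi in state0[1:]]

    dt = protocol.dt
    si = protocol.sample_interval if protocol.sample_interval is not None else dt
    sample_every = round(si / dt)

    names = state_names(params)[1:]
    t_out, v_out, i_cat_out, i_app_out = [], [], [], []
    x_out = [[] for _ in names]
    counter = [0]

    def record(t, i_app_now):
        t_out.append(t)
        v_out.append(v)
        for i, lst in enumerate(x_out):
            lst.append(x[i])
        i_cat_out.append(_i_cat_of(cat_entry, x, v))
        i_app_out.append(i_app_now)

    # segment boundaries fall exactly on grid points
    steps_per_seg = []
    for seg in protocol.segments:
        n_steps = round(seg.duration / dt)
        if not math.isclose(n_steps * dt, seg.duration, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"segment duration {seg.duration} ms is not a multiple of dt={dt} ms"
            )
        steps_per_seg.append(n_steps)

    first = protocol.segments[0]
    if first.v_clamp is not None:
        v = first.v_clamp
    record(0.0, first.i_app if first.v_clamp is None else 0.0)

    global_step = 0
    t_offset = 0.0
    for seg, n_steps in zip(protocol.segments, steps_per_seg):
        if seg.v_clamp is not None:
            v = seg.v_clamp
        for k in range(n_steps):
            v = step(gates_c, channels_c, c_m, v, x, seg.i_app, dt, seg.v_clamp)
            _guard_gates(x, counter)
            global_step += 1
            t_now = t_offset + (k + 1) * dt
            if not math.isfinite(v):
                raise IntegrationError(
                    f"non-finite membrane potential at t = {t_now:.4f} ms"
                )
            if global_step % sample_every == 0:
                record(global_step * dt, seg.i_app if seg.v_clamp is None else 0.0)
        t_offset += n_steps * dt

    if counter[0] > 0:
        logger.warning("gate clamp guard triggered %d time(s)", counter[0])

    return Trace(
        t=np.asarray(t_out),
        v=np.asarray(v_out),
        gates={name: np.asarray(col) for name, col in zip(names, x_out)},
        i_cat=np.asarray(i_cat_out),
        i_app=np.asarray(i_app_out),
        segment_boundaries=protocol.boundaries(),
        dt=dt,
        sample_interval=si,
        n_clamp_events=counter[0],
        method=method,
    )


@dataclass
class SettleResult:
    """Outcome of :func:`settle_to_rhythm`.

    ``status`` is ``"rhythmic"`` (interspike-interval CV of the last 10 ISIs
    dropped below the tolerance), ``"quiescent"`` (no spikes within
    ``max_time``) or ``"nonstationary"`` (spikes but no convergence).
    ``frequency`` is the mean instantaneous frequency of those last 10 ISIs
    (spikes/s; 0 when quiescent).
    """

    state: np.ndarray
    frequency: float
    status: str
    elapsed_ms: float
    isi_cv: float = math.nan
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rhythmic(self) -> bool:
        return self.status == "rhythmic"


def settle_to_rhythm(
    params: NeuronParams,
    i_app: float,
    max_time: float = 4000.0,
    dt: float = 0.02,
    cv_tol: float = 0.01,
    n_intervals: int = 10,
    threshold: float = -20.0,
    refractory: float = 2.0,
    chunk: float = 100.0,
    method: str = "exponential-euler",
) -> SettleResult:
    """Run at constant current until the firing rhythm is stationary.

    Integrates from the steady-state-at-rest initial condition in chunks,
    detecting spikes as it goes, and stops as soon as the coefficient of
    variation of the last ``n_intervals`` interspike intervals falls below
    ``cv_tol``.  Quiescence or non-convergence is reported in the result's
    ``status`` rather than raised.
    """
    gates_c, channels_c, cat_entry, c_m = _compile(params)
    step = _step_expeuler if method == "exponential-euler" else _step_rk4
    state0 = steady_state_vector(params, -65.0)
    v = float(state0[0])
    x = [float(xi) for xi in state0[1:]]
    counter = [0]

    n_chunk = round(chunk / dt)
    n_total = round(max_time / dt)

    spike_times: list[float] = []
    prev_v = v
    prev_t = 0.0
    last_spike = -math.inf
    done = 0
    cv = math.nan
    while done < n_total:
        n_now = min(n_chunk, n_total - done)
        for k in range(n_now):
            v_new = step(gates_c, channels_c, c_m, v, x, i_app, dt, None)
            _guard_gates(x, counter)
            t_new = (done + k + 1) * dt
            if not math.isfinite(v_new):
                raise IntegrationError(
                    f"non-finite membrane potential at t = {t_new:.4f} ms"
                )
            if prev_v < threshold <= v_new:
                t_cross = prev_t + (threshold - prev_v) / (v_new - prev_v) * dt
                if t_cross - last_spike >= refractory:
                    spike_times.append(t_cross)
                    last_spike = t_cross
            prev_v, prev_t, v = v_new, t_new, v_new
        done += n_now
        if len(spike_times) >= n_intervals + 1:
            isis = np.diff(spike_times[-(n_intervals + 1):])
            cv = float(np.std(isis) / np.mean(isis))
            if cv < cv_tol:
                freq = float(np.mean(1000.0 / isis))
                return SettleResult(
                    state=np.array([v] + x),
                    frequency=freq,
                    status="rhythmic",
                    elapsed_ms=done * dt,
                    isi_cv=cv,
                    spike_times=np.asarray(spike_times),
                )
    status = "quiescent" if len(spike_times) == 0 else "nonstationary"
    return SettleResult(
        state=np.array([v] + x),
        frequency=0.0,
        status=status,
        elapsed_ms=done * dt,
        isi_cv=cv,
        spike_times=np.asarray(spike_times),
    )
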