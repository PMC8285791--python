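"""Single-compartment current-balance model with an optional T-type current.

The membrane obeys

    c_m dV/dt = i_app - I_Na - I_K - I_leak - I_CaT

with each ionic current of the form g_max * prod(x_i^p_i) * (V - e_rev) and
every gate x_i following first-order kinetics from :mod:`tburst.gating`.  The
spiking backbone (Na, K, leak) is deliberately temperature-invariant; all
temperature and isoform dependence enters through the single ``CaTParams``
slot, so swapping a Cav3.1/3.2/3.3 kinetic set at 21 or 37 degC is a pure
parameter change.

State vectors are flat float arrays ``[V, gate_0, ..., gate_{n-1}]`` in the
order given by :func:`state_names`; :func:`rhs` is the reference right-hand
side that the integrators in :mod:`tburst.simulate` must agree with.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gating import ACTIVATION, INACTIVATION, GateSpec, steady_state, time_constant

__all__ = [
    "Channel",
    "CaTParams",
    "NeuronParams",
    "i_cat",
    "state_names",
    "gate_specs",
    "steady_state_vector",
    "rhs",
    "without_cat",
    "with_cat",
]


@dataclass(frozen=True)
class Channel:
    """One ohmic conductance: density (mS/cm^2), reversal (mV), named gates."""

    g_max: float
    e_rev: float
    gates: tuple[tuple[str, GateSpec], ...] = ()

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g_max) and self.g_max >= 0):
            raise ValueError(f"g_max must be finite and >= 0, got {self.g_max}")
        if not np.isfinite(self.e_rev):
            raise ValueError("e_rev must be finite")


@dataclass(frozen=True)
class CaTParams:
    """One (isoform, temperature) T-type calcium current variant.

    ``g_max`` is the maximal conductance density (mS/cm^2), ``e_rev`` the
    ohmic reversal potential (mV).  ``activation`` (gate m, raised to its own
    exponent) must have activation polarity and ``inactivation`` (gate h,
    linear) inactivation polarity; the inactivation gate's ``tau_hyper`` is
    the recovery-from-inactivation time constant.
    """

    isoform_label: str
    temperature_label: str
    g_max: float
    e_rev: float
    activation: GateSpec
    inactivation: GateSpec

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g_max) and self.g_max >= 0):
            raise ValueError(f"CaT g_max must be finite and >= 0, got {self.g_max}")
        if not np.isfinite(self.e_rev):
            raise ValueError("CaT e_rev must be finite")
        if self.activation.polarity != ACTIVATION:
            raise ValueError("CaT activation gate must have activation polarity")
        if self.inactivation.polarity != INACTIVATION:
            raise ValueError("CaT inactivation gate must have inactivation polarity")

    def as_channel(self) -> Channel:
        return Channel(
            g_max=self.g_max,
            e_rev=self.e_rev,
            gates=(("m", self.activation), ("h", self.inactivation)),
        )


@dataclass(frozen=True)
class NeuronParams:
    """Baseline spiker (Na, K, leak) plus an optional CaT slot.

    The Na/K/leak parameters carry no temperature dependence by construction;
    the model with ``cat=None`` is a tonic spiker over a documented applied
    current range (see the shipped default parameter set).
    """

    c_m: float
    na: Channel
    k: Channel
    leak: Channel
    cat: CaTParams | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_m) and self.c_m > 0):
            raise ValueError(f"c_m must be positive, got {self.c_m}")

    def channels(self) -> tuple[tuple[str, Channel], ...]:
        chans = [("na", self.na), ("k", self.k), ("leak", self.leak)]
        if self.cat is not None:
            chans.append(("cat", self.cat.as_channel()))
        return tuple(chans)


def without_cat(params: NeuronParams) -> NeuronParams:
    """Copy of ``params`` with the CaT slot removed."""
    return replace(params, cat=None)


def with_cat(params: NeuronParams, cat: CaTParams | None) -> NeuronParams:
    """Copy of ``params`` with the CaT slot replaced."""
    return replace(params, cat=cat)


def i_cat(cat: CaTParams, v: float, m: float, h: float) -> float:
    """T-type current density g_max * m^p * h * (V - e_rev) in uA/cm^2.

    Negative (inward) for V below the reversal potential.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"m must lie in [0, 1], got {m}")
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"h must lie in [0, 1], got {h}")
    return cat.g_max * m ** cat.activation.exponent * h * (v - cat.e_rev)


def gate_specs(params: NeuronParams) -> tuple[tuple[str, GateSpec], ...]:
    """Flat ``(name, spec)`` gate list in state-vector order (na, k, cat)."""
    out = []
    for chan_name, chan in params.channels():
        for gate_name, spec in chan.gates:
            out.append((f"{chan_name}_{gate_name}", spec))
    return tuple(out)


def state_names(params: NeuronParams) -> tuple[str, ...]:
    """Names of the state-vector components: ``("v", gate names...)``."""
    return ("v",) + tuple(name for name, _ in gate_specs(params))


def steady_state_vector(params: NeuronParams, v0: float) -> np.ndarray:
    """State with V = v0 and every gate at its steady state for v0."""
    gates = [steady_state(spec, v0) for _, spec in gate_specs(params)]
    return np.array([v0] + gates, dtype=float)


def _check_state(params: NeuronParams, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    n = 1 + len(gate_specs(params))
    if state.shape != (n,):
        raise ValueError(f"state must have shape ({n},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    return state


def rhs(params: NeuronParams, state: np.ndarray, i_app: float) -> np.ndarray:
    """Time derivatives of the state vector under applied current i_app.

    dV/dt = (i_app - sum of ionic currents)/c_m (mV/ms); each gate relaxes as
    (x_inf(V) - x)/tau_x(V).  Reference implementation used to cross-check the
    fast integrator loops.
    """
    state = _check_state(params, state)
    v = state[0]
    deriv = np.empty_like(state)
    i_ion = 0.0
    idx = 1
    for _, chan in params.channels():
        open_frac = 1.0
        for _, spec in chan.gates:
            open_frac *= state[idx] ** spec.exponent
            deriv[idx] = (steady_state(spec, v) - state[idx]) / time_constant(spec, v)
            idx += 1
        i_ion += chan.g_max * open_frac * (v - chan.e_rev)
    deriv[0] = (i_app - i_ion) / params.c_m
    return deriv


def make_zero_cat() -> CaTParams:
    """A CaT slot with zero conductance: contributes exactly nothing.

    Useful as an explicit control — trajectories with this slot inserted are
    bit-identical to trajectories with the slot absent.
    """
    act = GateSpec(
        v_half=-50.0, slope=6.0, polarity=ACTIVATION,
        tau_depol=1.5, tau_hyper=6.0, tau_v_mid=-45.0, tau_slope=8.0, exponent=2,
    )
    inact = GateSpec(
        v_half=-75.0, slope=6.0, polarity=INACTIVATION,
        tau_depol=25.0, tau_hyper=60.0, tau_v_mid=-70.0, tau_slope=6.0, exponent=1,
    )
    return CaTParams(
        isoform_label="zero", temperature_label="control",
        g_max=0.0, e_rev=120.0, activation=act, inactivation=inact,
    )


def default_neuron(cat: CaTParams | None = None) -> NeuronParams:
    """The shipped baseline spiking model, optionally with a CaT inserted.

    Loaded from the packaged default parameter file (see
    ``tburst/data/default_neuron.yaml``); tonic, temperature-invariant, with
    a documented operating range of roughly 3-10 uA/cm^2 applied current.
    """
    from . import params_io  # deferred: params_io imports this module

    params = params_io.load_default_baseline()
    return with_cat(params, cat) if cat is not None else params


__all__ += ["make_zero_cat", "default_neuron"]
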