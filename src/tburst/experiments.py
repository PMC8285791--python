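"""The two headline experiments, as library functions.

``run_rebound_experiment`` reproduces the rebound protocol: establish tonic
firing at a depolarizing holding current (+3 uA/cm^2 by default), hyperpolarize
(-5 uA/cm^2) for 70 ms, return to the holding current, and measure the burst
of spikes that follows release — peak instantaneous frequency, time to peak,
and decay back to the tonic rate.

``run_steady_state_experiment`` measures the tonic (steady-state) firing
frequency at the holding current with the T-type current inserted versus
removed; any persistent difference is carried by the window current.

The CLI (:mod:`tburst.cli`) is a thin shell over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CaTParams, NeuronParams, with_cat, without_cat
from .simulate import Protocol, Segment, SettleResult, Trace, integrate, settle_to_rhythm
from .spikes import ReboundMetrics, SpikeTrain, detect_spikes, instantaneous_frequency, rebound_metrics

__all__ = [
    "standard_rebound_protocol",
    "ReboundResult",
    "run_rebound_experiment",
    "SteadyStateResult",
    "run_steady_state_experiment",
]

# Standard rebound protocol levels (uA/cm^2) and step length (ms)
HOLD_CURRENT = 3.0
STEP_CURRENT = -5.0
STEP_DURATION = 70.0


def standard_rebound_protocol(
    hold: float = HOLD_CURRENT,
    step: float = STEP_CURRENT,
    step_duration: float = STEP_DURATION,
    pre: float = 200.0,
    post: float = 500.0,
    dt: float = 0.02,
    init: str | np.ndarray = "settle",
) -> Protocol:
    """Hold -> hyperpolarize -> release, with tonic firing established first.

    The pre-step segment is held at the *post*-step depolarizing level, so
    the hyperpolarization interrupts an ongoing rhythm; the default initial
    state is the settled rhythm at that level.
    """
    return Protocol(
        segments=(
            Segment(i_app=hold, duration=pre),
            Segment(i_app=step, duration=step_duration),
            Segment(i_app=hold, duration=post),
        ),
        dt=dt,
        init=init,
    )


@dataclass
class ReboundResult:
    """Everything one rebound run produces."""

    params: NeuronParams
    protocol: Protocol
    trace: Trace
    train: SpikeTrain
    settle: SettleResult
    release_time: float
    metrics: ReboundMetrics

    def frequency_series(self) -> pd.DataFrame:
        return instantaneous_frequency(self.train)


def run_rebound_experiment(
    params: NeuronParams,
    hold: float = HOLD_CURRENT,
    step: float = STEP_CURRENT,
    step_duration: float = STEP_DURATION,
    pre: float = 200.0,
    post: float = 500.0,
    dt: float = 0.02,
    method: str = "exponential-euler",
    threshold: float = -20.0,
    refractory: float = 2.0,
    band: float = 0.1,
) -> ReboundResult:
    """Run the standard rebound protocol on one parameter set.

    The pre-step steady frequency comes from settling at the holding current;
    the settled state also seeds the protocol, so the recorded pre-step
    segment continues an established rhythm.  Returns the trace, spike train
    and :class:`~tburst.spikes.ReboundMetrics`.
    """
    settle = settle_to_rhythm(
        params, hold, dt=dt, threshold=threshold, refractory=refractory, method=method
    )
    protocol = standard_rebound_protocol(
        hold=hold, step=step, step_duration=step_duration, pre=pre, post=post, dt=dt,
        init=settle.state,
    )
    trace = integrate(params, protocol, method=method)
    train = detect_spikes(trace, threshold=threshold, refractory=refractory)
    release = pre + step_duration
    metrics = rebound_metrics(
        train, release_time=release, steady_frequency=settle.frequency, band=band
    )
    return ReboundResult(
        params=params,
        protocol=protocol,
        trace=trace,
        train=train,
        settle=settle,
        release_time=release,
        metrics=metrics,
    )


@dataclass
class SteadyStateResult:
    """Tonic firing frequency with vs without the T-type current."""

    frequency_with_cat: float
    frequency_without_cat: float
    status_with_cat: str
    status_without_cat: str

    @property
    def delta(self) -> float:
        return self.frequency_with_cat - self.frequency_without_cat

    @property
    def delta_percent(self) -> float:
        base = self.frequency_without_cat
        return 100.0 * self.delta / base if base > 0 else float("nan")


def run_steady_state_experiment(
    params: NeuronParams,
    i_app: float = HOLD_CURRENT,
    dt: float = 0.02,
    method: str = "exponential-euler",
    **settle_kwargs,
) -> SteadyStateResult:
    """Steady-state firing with the CaT inserted vs removed, same baseline."""
    if params.cat is None:
        raise ValueError("params must carry a CaT set for the with/without contrast")
    res_with = settle_to_rhythm(params, i_app, dt=dt, method=method, **settle_kwargs)
    res_without = settle_to_rhythm(
        without_cat(params), i_app, dt=dt, method=method, **settle_kwargs
    )
    return SteadyStateResult(
        frequency_with_cat=res_with.frequency,
        frequency_without_cat=res_without.frequency,
        status_with_cat=res_with.status,
        status_without_cat=res_without.status,
    )
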