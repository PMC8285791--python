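"""Spike detection, instantaneous frequency, and rebound-burst metrics.

Spikes are upward threshold crossings of the sampled membrane potential,
linearly interpolated between samples, with a refractory window suppressing
double counts.  Instantaneous frequency is the reciprocal of each interspike
interval (ISI), reported at the time of the second spike of the pair — the
convention used when plotting firing frequency against time since the end of
a hyperpolarizing step.

Rebound metrics quantify the burst that follows release from
hyperpolarization: the peak instantaneous frequency, how long after release
it occurs, and how long the frequency takes to decay back into a band around
the pre-step steady rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "ReboundMetrics",
    "detect_spikes",
    "detect_spikes_from_arrays",
    "instantaneous_frequency",
    "rebound_metrics",
    "rebound_metrics_from_points",
    "f_i_curve",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) with the detection settings used."""

    times: np.ndarray
    threshold: float
    refractory: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1:
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(gaps < self.refractory - 1e-9):
                raise ValueError("spike times violate the refractory window")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ReboundMetrics:
    """Summary of one rebound run.

    ``decay_time`` is measured from the frequency peak until the
    instantaneous frequency first returns within ``band`` (relative) of
    ``steady_frequency``.  When no spike follows the release,
    ``peak_frequency`` is 0 and the time fields are NaN with ``defined``
    False; ``decay_time`` is NaN if the frequency never re-enters the band
    within the recorded window.
    """

    steady_frequency: float
    peak_frequency: float
    time_to_peak: float
    decay_time: float
    rebound_ratio: float
    defined: bool = True
    band: float = 0.1


def detect_spikes_from_arrays(
    t: np.ndarray, v: np.ndarray, threshold: float = -20.0, refractory: float = 2.0
) -> SpikeTrain:
    """Threshold-crossing spike detection on a uniformly sampled (t, v) pair."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("t and v must be one-dimensional arrays of equal length")
    times = []
    last = -math.inf
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    for i in np.nonzero(below & above)[0]:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t_cross = t[i] + frac * (t[i + 1] - t[i])
        if t_cross - last >= refractory:
            times.append(t_cross)
            last = t_cross
    return SpikeTrain(np.asarray(times), threshold, refractory)


def detect_spikes(trace, threshold: float = -20.0, refractory: float = 2.0) -> SpikeTrain:
    """Detect spikes on a :class:`~tburst.simulate.Trace`.

    A threshold that the voltage never reaches yields an empty train, not an
    error.
    """
    return detect_spikes_from_arrays(trace.t, trace.v, threshold, refractory)


def instantaneous_frequency(train: SpikeTrain) -> pd.DataFrame:
    """1000/ISI (spikes/s) at the time of the second spike of each ISI.

    Returns a two-column frame ``(time_ms, frequency_hz)``; empty for fewer
    than two spikes.
    """
    t = train.times
    if t.size < 2:
        return pd.DataFrame({"time_ms": [], "frequency_hz": []})
    isi = np.diff(t)
    return pd.DataFrame({"time_ms": t[1:], "frequency_hz": 1000.0 / isi})


def rebound_metrics(
    train: SpikeTrain,
    release_time: float,
    steady_frequency: float,
    band: float = 0.1,
) -> ReboundMetrics:
    """Rebound-burst metrics relative to the end of the hyperpolarization.

    The peak is taken over instantaneous-frequency points at or after
    ``release_time`` (ties broken by earliest time); ``time_to_peak`` is the
    peak's time minus ``release_time``; ``decay_time`` runs from the peak to
    the first point whose frequency lies within ``band`` (relative, default
    10%) of ``steady_frequency`` — zero if the peak itself is in the band.
    """
    freqs = instantaneous_frequency(train)
    return rebound_metrics_from_points(
        freqs["time_ms"].to_numpy(),
        freqs["frequency_hz"].to_numpy(),
        release_time,
        steady_frequency,
        band=band,
    )


def rebound_metrics_from_points(
    times: np.ndarray,
    frequencies: np.ndarray,
    release_time: float,
    steady_frequency: float,
    band: float = 0.1,
) -> ReboundMetrics:
    """Rebound metrics on an explicit (time, instantaneous frequency) series.

    Core of :func:`rebound_metrics`; useful when the frequency series comes
    from somewhere other than a spike train.
    """
    times = np.asarray(times, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    keep = times >= release_time
    if not np.any(keep):
        return ReboundMetrics(
            steady_frequency=steady_frequency,
            peak_frequency=0.0,
            time_to_peak=math.nan,
            decay_time=math.nan,
            rebound_ratio=math.nan,
            defined=False,
            band=band,
        )
    f = frequencies[keep]
    t = times[keep]
    i_peak = int(np.argmax(f))  # argmax returns the first maximum: earliest time
    peak = float(f[i_peak])
    t_peak = float(t[i_peak])
    lo = steady_frequency * (1.0 - band)
    hi = steady_frequency * (1.0 + band)
    decay = math.nan
    in_band = (f[i_peak:] >= lo) & (f[i_peak:] <= hi)
    hits = np.nonzero(in_band)[0]
    if hits.size > 0:
        decay = float(t[i_peak + hits[0]] - t_peak)
    ratio = peak / steady_frequency if steady_frequency > 0 else math.nan
    return ReboundMetrics(
        steady_frequency=steady_frequency,
        peak_frequency=peak,
        time_to_peak=t_peak - release_time,
        decay_time=decay,
        rebound_ratio=ratio,
        defined=True,
        band=band,
    )


def f_i_curve(params, i_values, **settle_kwargs) -> pd.DataFrame:
    """Steady-state frequency at each applied current (f-I curve).

    One :func:`~tburst.simulate.settle_to_rhythm` call per current; quiescent
    or non-stationary points report frequency 0 with their status.  Returns a
    frame with columns ``i_app_ua_cm2``, ``frequency_hz``, ``status``.
    """
    from .simulate import settle_to_rhythm  # deferred to avoid an import cycle

    rows = []
    for i_app in i_values:
        if not np.isfinite(i_app):
            raise ValueError("applied currents must be finite")
        res = settle_to_rhythm(params, float(i_app), **settle_kwargs)
        rows.append(
            {
                "i_app_ua_cm2": float(i_app),
                "frequency_hz": res.frequency if res.rhythmic else 0.0,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)
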