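"""Averaged extracellular AP waveform metrics.

Dopamine neurons are screened in vivo by a broad biphasic extracellular
action potential (> 1.2 ms from the start of the initial upward
component to the minimum of the following downward component) and a slow
firing rate (1-8 Hz).  The relative AP trough is that minimum after
normalising the peak amplitude to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Waveform",
    "APMetrics",
    "DAIdentificationCriteria",
    "load_waveform",
    "average_waveform",
    "ap_metrics",
    "is_putative_da",
]


@dataclass(frozen=True)
class Waveform:
    """High-resolution averaged AP trace.

    voltage is in mV per sample; ``baseline_window`` is the (start, stop)
    sample range used for baseline mean/SD (must precede the peak).  When
    None it defaults to the first quarter of the samples before the peak.
    """

    voltage: np.ndarray
    sample_interval: float  # seconds per sample
    baseline_window: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if v.size * self.sample_interval < 0.002:
            raise ValueError("waveform must cover at least 2 ms")

    def resolved_baseline(self) -> tuple[int, int]:
        if self.baseline_window is not None:
            a, b = self.baseline_window
            return int(a), int(b)
        peak = int(np.argmax(self.voltage))
        return 0, max(2, peak // 4)


@dataclass(frozen=True)
class APMetrics:
    duration_ms: float  # onset of the upward component -> post-peak minimum
    relative_trough: float  # trough voltage with peak scaled to 1 (negative)
    peak_index: int
    trough_index: int
    onset_index: int


@dataclass(frozen=True)
class DAIdentificationCriteria:
    min_duration_ms: float = 1.2
    rate_band_hz: tuple = (1.0, 8.0)

    def __post_init__(self) -> None:
        if self.rate_band_hz[0] >= self.rate_band_hz[1]:
            raise ValueError("rate band low must be below high")


def load_waveform(path, baseline_window=None) -> Waveform:
    """Two-column delimited text (time_s, voltage_mV) -> Waveform."""
    arr = np.loadtxt(path, delimiter=None if str(path).endswith(".txt") else ",",
                     comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("expected two columns: time_s, voltage_mV")
    dt = float(np.median(np.diff(arr[:, 0])))
    return Waveform(arr[:, 1], dt, baseline_window)


def average_waveform(aligned_sweeps: list[Waveform]) -> Waveform:
    """Peak-align and average sweeps; re-zero to the pre-peak baseline.

    Requires equal lengths and sampling.  Fewer than 10 sweeps triggers a
    warning (the average is still computed).  Sweeps are shifted so every
    peak sits at the median peak index (edge samples replicated).
    """
    if not aligned_sweeps:
        raise ValueError("no sweeps given")
    n = aligned_sweeps[0].voltage.size
    dt = aligned_sweeps[0].sample_interval
    for w in aligned_sweeps:
        if w.voltage.size != n:
            raise ValueError("sweeps must have equal length")
        if abs(w.sample_interval - dt) > 1e-12:
            raise ValueError("sweeps must share one sampling interval")
    if len(aligned_sweeps) < 10:
        warnings.warn("fewer than 10 sweeps averaged; waveform metrics may "
                      "be noisy", stacklevel=2)
    peaks = np.array([int(np.argmax(w.voltage)) for w in aligned_sweeps])
    target = int(np.median(peaks))
    stack = np.empty((len(aligned_sweeps), n))
    for i, (w, pk) in enumerate(zip(aligned_sweeps, peaks)):
        shift = target - pk
        v = w.voltage
        if shift > 0:
            stack[i] = np.concatenate([np.full(shift, v[0]), v[:-shift]])
        elif shift < 0:
            stack[i] = np.concatenate([v[-shift:], np.full(-shift, v[-1])])
        else:
            stack[i] = v
    mean = stack.mean(axis=0)
    bl = aligned_sweeps[0].baseline_window
    out = Waveform(mean, dt, bl)
    a, b = out.resolved_baseline()
    return Waveform(mean - mean[a:b].mean(), dt, bl)


def ap_metrics(w: Waveform, onset_sd_mult: float = 3.0,
               min_trough_frac: float = 0.02) -> APMetrics:
    """AP duration (ms) and relative trough of a biphasic waveform.

    The onset of the initial upward component is the last sample before
    the voltage first exceeds baseline mean + ``onset_sd_mult`` * baseline
    SD ahead of the peak; the duration runs from there to the post-peak
    minimum.  The relative trough is the trough voltage after scaling the
    baseline-subtracted peak to 1.  A waveform without a post-peak
    negative deflection is monophasic and raises ValueError.
    """
    a, b = w.resolved_baseline()
    v = w.voltage - w.voltage[a:b].mean()
    sd = float(w.voltage[a:b].std())
    peak = int(np.argmax(v))
    if peak >= v.size - 1 or v[peak] <= 0:
        raise ValueError("no positive peak followed by samples")
    trough = peak + int(np.argmin(v[peak:]))
    if v[trough] >= -min_trough_frac * v[peak]:
        raise ValueError("monophasic waveform: no post-peak trough")
    thr = onset_sd_mult * sd
    above = np.nonzero(v[:peak + 1] > thr)[0]
    crossing = int(above[0]) if above.size else peak
    onset = max(crossing - 1, 0)
    duration_ms = (trough - onset) * w.sample_interval * 1e3
    return APMetrics(duration_ms, float(v[trough] / v[peak]), peak, trough,
                     onset)


def is_putative_da(metrics: APMetrics, rate: float,
                   criteria: DAIdentificationCriteria =
                   DAIdentificationCriteria()) -> bool:
    """Broad biphasic AP (> 1.2 ms) and slow rate (1-8 Hz) screen."""
    lo, hi = criteria.rate_band_hz
    return bool(metrics.duration_ms > criteria.min_duration_ms
                and lo <= rate <= hi)
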