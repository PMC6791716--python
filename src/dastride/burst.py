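"""Burst and pause detection for dopamine-neuron spike trains.

Bursts follow the classical in-vivo criterion for nigral dopamine
neurons: a burst opens at an interspike interval shorter than 80 ms and
extends while subsequent intervals stay below 160 ms.  Burstiness is
summarised as SFB, the percentage of spikes fired in bursts, with cells
above 5% SFB called bursty.

Pauses are quantile outliers of the ISI distribution: an interval longer
than ``pthr = q3 + w * (q3 - q1)`` with w = 3, where q1/q3 are the ISI
quartiles.  Intervals immediately following a burst are excluded by
default, since post-burst quiescence may be of non-synaptic origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spiketrain import SpikeTrain

__all__ = [
    "BurstCriteria",
    "Burst",
    "BurstStats",
    "PauseCriteria",
    "PauseStats",
    "detect_bursts",
    "burst_stats",
    "pause_threshold",
    "detect_pauses",
]


@dataclass(frozen=True)
class BurstCriteria:
    onset_isi_max: float = 0.080  # s; ISI strictly below this opens a burst
    continuation_isi_max: float = 0.160  # s; ISI strictly below this extends it
    sfb_bursty_threshold: float = 5.0  # percent; strictly above -> bursty

    def __post_init__(self) -> None:
        if not (0 < self.onset_isi_max <= self.continuation_isi_max):
            raise ValueError("require 0 < onset <= continuation ISI cut")
        if not (0 <= self.sfb_bursty_threshold <= 100):
            raise ValueError("SFB threshold must be in [0, 100]")


@dataclass(frozen=True)
class Burst:
    """One detected burst: inclusive spike-index range into the train."""

    first_spike_index: int
    last_spike_index: int
    mean_intraburst_rate: float  # Hz, 1 / mean(intraburst ISIs)

    @property
    def n_spikes(self) -> int:
        return self.last_spike_index - self.first_spike_index + 1


@dataclass(frozen=True)
class BurstStats:
    sfb: float  # percent of spikes inside bursts
    bursts_per_min: float
    mean_intraburst_rate: float  # Hz; NaN when no bursts
    is_bursty: bool  # sfb strictly > threshold
    n_bursts: int


@dataclass(frozen=True)
class PauseCriteria:
    quantile_low: float = 0.25
    quantile_high: float = 0.75
    w_factor: float = 3.0
    exclude_post_burst: bool = True
    quantile_method: str = "linear"  # numpy quantile method ("type 7")

    def __post_init__(self) -> None:
        if not (0 < self.quantile_low < self.quantile_high < 1):
            raise ValueError("require 0 < q_low < q_high < 1")
        if self.w_factor <= 0:
            raise ValueError("w_factor must be positive")


@dataclass(frozen=True)
class PauseStats:
    threshold_pthr: float  # seconds; NaN when not computable
    pauses_per_min: float
    mean_pause_duration: float  # seconds; NaN when no pauses
    pause_isi_indices: tuple = field(default_factory=tuple)


def detect_bursts(train: SpikeTrain,
                  criteria: BurstCriteria = BurstCriteria()) -> list[Burst]:
    """Left-to-right scan applying the onset/continuation ISI rule.

    A burst opens at the first spike of an ISI < ``onset_isi_max`` and
    extends while following ISIs are < ``continuation_isi_max``; the
    closing spike is the one before the first ISI at or above the
    continuation cut.  Spikes belong to at most one burst; bursts are
    disjoint and ordered and contain >= 2 spikes.
    """
    isis = train.isis
    n_isi = isis.size
    bursts: list[Burst] = []
    i = 0
    while i < n_isi:
        if isis[i] < criteria.onset_isi_max:
            j = i + 1
            while j < n_isi and isis[j] < criteria.continuation_isi_max:
                j += 1
            intraburst = isis[i:j]
            bursts.append(Burst(i, j, 1.0 / float(intraburst.mean())))
            i = j + 1  # spike j closed the burst; next onset ISI starts at j+1
        else:
            i += 1
    return bursts


def burst_stats(train: SpikeTrain, bursts: list[Burst],
                criteria: BurstCriteria = BurstCriteria(),
                span: float | None = None) -> BurstStats:
    """SFB (%), burst rate and mean intraburst frequency of one train.

    ``span`` is the analysed duration in seconds (defaults to the train's
    nominal duration); the intraburst frequency is the unweighted mean of
    per-burst mean rates and is NaN for cells without bursts.
    """
    if span is None:
        span = train.duration
    n = train.n_spikes
    in_burst = sum(b.n_spikes for b in bursts)
    sfb = 100.0 * in_burst / n if n else 0.0
    bursts_per_min = 60.0 * len(bursts) / span
    mean_ib = (float(np.mean([b.mean_intraburst_rate for b in bursts]))
               if bursts else float("nan"))
    return BurstStats(sfb, bursts_per_min, mean_ib,
                      sfb > criteria.sfb_bursty_threshold, len(bursts))


def pause_threshold(isis, criteria: PauseCriteria = PauseCriteria()) -> float:
    """Tukey-style outlier cut pthr = q3 + w * (q3 - q1) on the ISI sample.

    Returns NaN for fewer than 4 ISIs (quartiles too unstable to define a
    per-cell threshold).
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 4:
        return float("nan")
    q1, q3 = np.quantile(isis, [criteria.quantile_low, criteria.quantile_high],
                         method=criteria.quantile_method)
    return float(q3 + criteria.w_factor * (q3 - q1))


def detect_pauses(train: SpikeTrain, bursts: list[Burst],
                  criteria: PauseCriteria = PauseCriteria(),
                  span: float | None = None) -> PauseStats:
    """Identify pauses: ISIs above pthr, excluding post-burst intervals.

    An ISI is a pause when it exceeds the cell's threshold and (with
    ``exclude_post_burst``) its opening spike is not the closing spike of
    a detected burst.
    """
    if span is None:
        span = train.duration
    isis = train.isis
    pthr = pause_threshold(isis, criteria)
    if np.isnan(pthr):
        return PauseStats(pthr, float("nan"), float("nan"), ())
    burst_ends = {b.last_spike_index for b in bursts} \
        if criteria.exclude_post_burst else set()
    idx = tuple(i for i in np.nonzero(isis > pthr)[0] if i not in burst_ends)
    durations = isis[list(idx)] if idx else np.empty(0)
    return PauseStats(
        pthr,
        60.0 * len(idx) / span,
        float(durations.mean()) if len(idx) else float("nan"),
        idx,
    )
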