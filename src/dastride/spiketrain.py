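"""Spike-train container, ISI statistics and autocorrelograms.

The atomic observable of the whole pipeline is a sorted series of spike
timestamps (seconds) recorded from one neuron.  Everything downstream —
burst and pause detection, stationarity segmentation, oscillator fitting,
group statistics — operates on :class:`SpikeTrain`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "Autocorrelogram",
    "load_spike_times",
    "isi_stats",
    "autocorrelogram",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron.

    Parameters
    ----------
    times
        Spike timestamps in seconds, strictly increasing, all within
        ``[0, duration]``.
    duration
        Length of the analysed recording (or segment) in seconds.
    cell_id
        Opaque label carried through to result tables.
    """

    times: np.ndarray
    duration: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration + 1e-9:
                raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.times)

    @property
    def span(self) -> float:
        """Time between first and last spike (seconds); 0 if < 2 spikes."""
        if self.n_spikes < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def crop(self, start: float, end: float) -> "SpikeTrain":
        """Sub-train on ``[start, end]``, re-referenced so the segment starts at 0."""
        if not (0 <= start < end <= self.duration + 1e-9):
            raise ValueError("invalid crop window")
        sel = self.times[(self.times >= start) & (self.times <= end)]
        return SpikeTrain(sel - start, end - start, cell_id=self.cell_id)


@dataclass(frozen=True)
class ISIStats:
    """First-order ISI statistics; undefined fields are NaN."""

    mean_rate: float  # Hz, (n-1) / span between first and last spike
    cv: float  # percent, 100 * sd(ISI) / mean(ISI)
    skewness: float
    kurtosis: float  # non-excess by default (normal -> 3)
    n_spikes: int


@dataclass(frozen=True)
class Autocorrelogram:
    """Autocorrelation histogram, normalised to rate per reference spike.

    ``rate[i]`` is (pair count in bin i) / (n_ref * bin_width), i.e. the
    empirical intensity (Hz) of observing another spike at that lag.  The
    zero-lag self pair is excluded; the histogram is symmetric in lag sign.
    """

    lag_bin_edges: np.ndarray  # seconds, length n_bins + 1, symmetric about 0
    rate: np.ndarray  # Hz per reference spike, length n_bins
    bin_width: float
    max_lag: float
    n_ref: int = 0  # number of reference spikes

    @property
    def lag_centers(self) -> np.ndarray:
        return 0.5 * (self.lag_bin_edges[:-1] + self.lag_bin_edges[1:])

    def positive_half(self) -> tuple[np.ndarray, np.ndarray]:
        """(lag centers, rate) restricted to strictly positive lags."""
        c = self.lag_centers
        pos = c > 0
        return c[pos], self.rate[pos]


_DURATION_RE = re.compile(r"#\s*duration\s*=\s*([0-9.eE+-]+)")


def load_spike_times(path, duration: float | None = None,
                     cell_id: str = "") -> SpikeTrain:
    """Read spike timestamps (one float per line, seconds) into a SpikeTrain.

    An optional header line ``#duration=<s>`` sets the recording length;
    an explicit ``duration`` argument overrides it.  Times are sorted and
    exact duplicates dropped.  Negative timestamps or an empty file are
    input errors.
    """
    times: list[float] = []
    file_duration = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _DURATION_RE.match(line)
                if m:
                    file_duration = float(m.group(1))
                continue
            # allow a delimited first column
            tok = re.split(r"[,\s;]+", line)[0]
            times.append(float(tok))
    if not times:
        raise ValueError(f"no spike times found in {path}")
    t = np.unique(np.asarray(times, dtype=float))
    if t[0] < 0:
        raise ValueError("negative spike timestamps are not allowed")
    if duration is None:
        duration = file_duration if file_duration is not None else float(t[-1])
    if duration <= 0:  # single spike at t=0
        raise ValueError("cannot infer a positive duration")
    return SpikeTrain(t, float(duration), cell_id=cell_id or str(path))


def isi_stats(train: SpikeTrain, excess_kurtosis: bool = False) -> ISIStats:
    """Mean rate, CV (%) and ISI-distribution shape of a spike train.

    mean_rate = (n-1)/(last-first); CV uses the sample SD (ddof=1) and
    needs >= 3 spikes; skewness/kurtosis are moment-based on the ISI
    sample and need >= 5 spikes.  Kurtosis is non-excess by default.
    Fields that cannot be computed are NaN rather than raising.
    """
    n = train.n_spikes
    mean_rate = cv = skw = kur = float("nan")
    if n >= 2 and train.span > 0:
        mean_rate = (n - 1) / train.span
    isis = train.isis
    if n >= 3:
        m = isis.mean()
        if m > 0:
            cv = 100.0 * isis.std(ddof=1) / m
    if n >= 5:
        import warnings
        with warnings.catch_warnings():
            # near-constant ISI samples (pacemakers) trip scipy's
            # catastrophic-cancellation warning; NaN moments are fine there
            warnings.simplefilter("ignore", RuntimeWarning)
            skw = float(scipy.stats.skew(isis))
            kur = float(scipy.stats.kurtosis(isis, fisher=excess_kurtosis))
    return ISIStats(mean_rate, cv, skw, kur, n)


def autocorrelogram(train: SpikeTrain, bin_width: float = 0.010,
                    max_lag: float = 2.0) -> Autocorrelogram:
    """Histogram of pairwise spike-time differences within +/- max_lag.

    Zero-lag self pairs are excluded.  Counts are normalised to a rate:
    pairs / (n_spikes * bin_width), so a homogeneous Poisson train of rate
    lambda gives a flat ACH at approximately lambda.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_lag < 10 * bin_width:
        raise ValueError("max_lag must be at least 10 * bin_width")
    t = train.times
    n = t.size
    half_bins = int(round(max_lag / bin_width))
    edges = np.arange(-half_bins, half_bins + 1) * bin_width
    if n < 2:
        return Autocorrelogram(edges, np.zeros(edges.size - 1), bin_width,
                               max_lag, n_ref=n)
    # forward differences only; mirror for negative lags
    hi = np.searchsorted(t, t + max_lag, side="right")
    diffs = np.concatenate([t[i + 1:hi[i]] - t[i] for i in range(n)]) \
        if n else np.empty(0)
    pos_counts, _ = np.histogram(diffs, bins=half_bins, range=(0.0, max_lag))
    counts = np.concatenate([pos_counts[::-1], pos_counts]).astype(float)
    rate = counts / (n * bin_width)
    return Autocorrelogram(edges, rate, bin_width, max_lag, n_ref=n)
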