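"""Multiple-filter change-point test for firing-rate stationarity.

For every filter window h and evaluation time t the statistic compares
the spike counts in (t-h, t] and (t, t+h], scaled by a local variance
estimate derived from the empirical ISI mean and variance in each window
(for a renewal process, Var(count in h) ~ h * var(ISI) / mean(ISI)^3).
The global statistic is the maximum over t and all windows; its
rejection threshold is the (1 - alpha) quantile of the same maximum
under simulated rate-homogeneous (Poisson) trains at the observed rate.
Detected change points partition the recording; the longest resulting
piece is the stationary segment used for oscillator fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrain import SpikeTrain

__all__ = ["StationarityResult", "multiple_filter_test", "mft_threshold"]

DEFAULT_WINDOWS = (25.0, 50.0, 100.0, 150.0)


@dataclass(frozen=True)
class StationarityResult:
    change_points: tuple  # seconds, strictly inside (0, duration)
    longest_segment: tuple  # (start, end) seconds
    windows_used: tuple
    alpha: float
    tested: bool  # False when the train was too short to test
    max_statistic: float = float("nan")
    threshold: float = float("nan")


def _filter_statistic(times: np.ndarray, duration: float, h: float,
                      grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    """|G_h(t)| on the evaluation grid for one window h."""
    t_grid = np.arange(h, duration - h + 1e-9, grid_step)
    if t_grid.size == 0:
        return t_grid, np.empty(0)
    isis = np.diff(times)
    cs1 = np.concatenate([[0.0], np.cumsum(isis)])
    cs2 = np.concatenate([[0.0], np.cumsum(isis ** 2)])

    def window_stats(a, b):
        lo = np.searchsorted(times, a, side="right")
        hi = np.searchsorted(times, b, side="right")
        count = hi - lo
        # ISIs fully inside (a, b]: indices lo .. hi-2
        n_isi = np.maximum(hi - 1 - lo, 0)
        s1 = cs1[np.maximum(hi - 1, 0)] - cs1[np.minimum(lo, cs1.size - 1)]
        s2 = cs2[np.maximum(hi - 1, 0)] - cs2[np.minimum(lo, cs2.size - 1)]
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(n_isi > 0, s1 / np.maximum(n_isi, 1), np.nan)
            v = np.where(n_isi > 1, s2 / np.maximum(n_isi, 1) - m ** 2, np.nan)
        return count, m, np.maximum(v, 0.0), n_isi

    nl, ml, vl, kl = window_stats(t_grid - h, t_grid)
    nr, mr, vr, kr = window_stats(t_grid, t_grid + h)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = h * (vl / ml ** 3 + vr / mr ** 3)
    g = np.zeros_like(t_grid)
    ok = (kl >= 2) & (kr >= 2) & np.isfinite(var) & (var > 0)
    g[ok] = np.abs(nr[ok] - nl[ok]) / np.sqrt(var[ok])
    return t_grid, g


def _max_statistic_profile(times: np.ndarray, duration: float,
                           windows, grid_step: float):
    """Pointwise max over windows of |G_h(t)| on the finest common grid."""
    h_min = min(windows)
    t_grid = np.arange(h_min, duration - h_min + 1e-9, grid_step)
    prof = np.zeros_like(t_grid)
    for h in windows:
        tg, g = _filter_statistic(times, duration, h, grid_step)
        if g.size == 0:
            continue
        # tg is a contiguous sub-grid of t_grid
        off = int(round((tg[0] - t_grid[0]) / grid_step))
        prof[off:off + g.size] = np.maximum(prof[off:off + g.size], g)
    return t_grid, prof


def mft_threshold(duration: float, rate: float, windows=DEFAULT_WINDOWS,
                  alpha: float = 0.05, n_null_sims: int = 1000,
                  seed=None, grid_step: float = 1.0) -> float:
    """(1-alpha) quantile of the max statistic under homogeneous Poisson.

    The statistic is studentised by local ISI moments and therefore close
    to pivotal in the rate; the threshold can be shared across trains of
    equal duration and comparable rate.
    """
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_null_sims)
    for i in range(n_null_sims):
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n))
        if n < 4:
            maxima[i] = 0.0
            continue
        _, prof = _max_statistic_profile(times, duration, windows, grid_step)
        maxima[i] = prof.max() if prof.size else 0.0
    return float(np.quantile(maxima, 1.0 - alpha))


def multiple_filter_test(train: SpikeTrain, windows=DEFAULT_WINDOWS,
                         alpha: float = 0.05, n_null_sims: int = 1000,
                         seed=None, grid_step: float = 1.0,
                         threshold: float | None = None) -> StationarityResult:
    """Detect rate change points; report the longest stationary segment.

    ``threshold`` may be supplied to reuse a precomputed null quantile
    (the statistic is approximately pivotal); otherwise it is simulated
    from ``n_null_sims`` homogeneous trains at the observed mean rate.
    Trains too short for every window (duration < 2 * min(windows)) or
    with < 4 spikes are returned untested as a single whole-train
    segment.
    """
    T = train.duration
    usable = tuple(h for h in windows if T >= 2 * h)
    if not usable or train.n_spikes < 4:
        return StationarityResult((), (0.0, T), usable, alpha, tested=False)
    rate = train.n_spikes / T
    if threshold is None:
        threshold = mft_threshold(T, rate, usable, alpha, n_null_sims,
                                  seed=seed, grid_step=grid_step)
    t_grid, prof = _max_statistic_profile(train.times, T, usable, grid_step)
    m_obs = float(prof.max()) if prof.size else 0.0
    cps: list[float] = []
    if m_obs > threshold:
        # candidate change points: argmax within each rejected excursion
        above = prof > threshold
        edges = np.flatnonzero(np.diff(above.astype(int)))
        runs = []
        s = 0 if above[0] else None
        for e in edges:
            if s is None:
                s = e + 1
            else:
                runs.append((s, e + 1))
                s = None
        if s is not None:
            runs.append((s, above.size))
        cands = []
        for a, b in runs:
            k = a + int(np.argmax(prof[a:b]))
            cands.append((prof[k], t_grid[k]))
        # enforce minimal segment length = max usable window
        min_sep = max(usable)
        for _, t_cp in sorted(cands, reverse=True):
            if all(abs(t_cp - c) >= min_sep for c in cps):
                cps.append(float(t_cp))
        cps.sort()
    bounds = [0.0] + cps + [T]
    segments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    # longest segment containing at least 2 spikes
    def n_in(seg):
        lo = np.searchsorted(train.times, seg[0], side="left")
        hi = np.searchsorted(train.times, seg[1], side="right")
        return hi - lo
    valid = [s for s in segments if n_in(s) >= 2] or segments
    longest = max(valid, key=lambda s: s[1] - s[0])
    return StationarityResult(tuple(cps), longest, usable, alpha,
                              tested=True, max_statistic=m_obs,
                              threshold=float(threshold))
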