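"""Burst detection (80/160 ms rule), SFB and pause detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dastride.burst import (BurstCriteria, PauseCriteria, burst_stats,
                            detect_bursts, detect_pauses, pause_threshold)
from dastride.spiketrain import SpikeTrain

from conftest import random_train


def oracle_burst_labels(times, onset=0.080, continuation=0.160):
    """Independent per-spike burst labelling by exhaustive scan.

    Walks the raw spike times, marking every spike with its burst index
    or -1; kept deliberately simple-minded (no vectorisation, no reuse of
    the implementation's ISI bookkeeping).
    """
    n = len(times)
    labels = [-1] * n
    b = -1
    k = 0
    while k < n - 1:
        if labels[k] == -1 and (times[k + 1] - times[k]) < onset:
            b += 1
            labels[k] = labels[k + 1] = b
            j = k + 1
            while j < n - 1 and (times[j + 1] - times[j]) < continuation:
                labels[j + 1] = b
                j += 1
            k = j + 1
        else:
            k += 1
    return labels


def labels_from_bursts(n, bursts):
    labels = [-1] * n
    for bi, b in enumerate(bursts):
        for k in range(b.first_spike_index, b.last_spike_index + 1):
            labels[k] = bi
    return labels


class TestDetectBursts:
    def test_no_subthreshold_isis(self):
        tr = SpikeTrain(np.arange(10) * 0.5, 5.0)
        assert detect_bursts(tr) == []

    def test_hand_worked_example(self):
        tr = SpikeTrain(np.array([0, 0.05, 0.15, 0.50, 0.56, 1.50]), 2.0)
        bursts = detect_bursts(tr)
        assert [(b.first_spike_index, b.last_spike_index) for b in bursts] \
            == [(0, 2), (3, 4)]
        st_ = burst_stats(tr, bursts)
        assert st_.sfb == pytest.approx(100 * 5 / 6)
        # intraburst rates: 1/mean(.05,.10) and 1/.06
        assert bursts[0].mean_intraburst_rate == pytest.approx(1 / 0.075)
        assert bursts[1].mean_intraburst_rate == pytest.approx(1 / 0.06)

    def test_continuation_alone_never_opens(self):
        # all ISIs exactly 100 ms: >= onset cut, < continuation cut
        tr = SpikeTrain(np.arange(20) * 0.1, 2.0)
        assert detect_bursts(tr) == []

    def test_boundary_is_strict(self):
        tr = SpikeTrain(np.array([0.0, 0.080, 0.2]), 1.0)
        assert detect_bursts(tr) == []  # exactly 80 ms does not open
        tr2 = SpikeTrain(np.array([0.0, 0.079, 0.239, 0.399]), 1.0)
        (b,) = detect_bursts(tr2)
        assert (b.first_spike_index, b.last_spike_index) == (0, 2)

    def test_matches_oracle_on_random_trains(self, rng):
        for _ in range(300):
            tr = random_train(rng)
            bursts = detect_bursts(tr)
            assert labels_from_bursts(tr.n_spikes, bursts) \
                == oracle_burst_labels(list(tr.times))

    @given(seed=st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_bursts_disjoint_ordered_and_sfb_bounded(self, seed):
        tr = random_train(np.random.default_rng(seed))
        bursts = detect_bursts(tr)
        last = -1
        for b in bursts:
            assert b.first_spike_index > last
            assert b.n_spikes >= 2
            last = b.last_spike_index
        s = burst_stats(tr, bursts)
        assert 0 <= s.sfb <= 100

    def test_time_rescaling(self, rng):
        tr = random_train(rng)
        doubled = SpikeTrain(tr.times * 2, tr.duration * 2)
        crit2 = BurstCriteria(onset_isi_max=0.16, continuation_isi_max=0.32)
        b1 = detect_bursts(tr)
        b2 = detect_bursts(doubled, crit2)
        assert [(b.first_spike_index, b.last_spike_index) for b in b1] \
            == [(b.first_spike_index, b.last_spike_index) for b in b2]
        for a, b in zip(b1, b2):
            assert b.mean_intraburst_rate == pytest.approx(
                a.mean_intraburst_rate / 2)


class TestBurstStats:
    def test_bursts_per_min(self):
        tr = SpikeTrain(np.array([0, .05, .1, 30, 30.05, 30.1, 59]), 60.0)
        bursts = detect_bursts(tr)
        assert burst_stats(tr, bursts).bursts_per_min == pytest.approx(2.0)

    def test_mean_intraburst_rate_unweighted(self):
        # two bursts with intraburst ISI means 75 ms and 60 ms
        tr = SpikeTrain(np.array([0, .075, .15, 10, 10.06, 20]), 60.0)
        s = burst_stats(tr, detect_bursts(tr))
        assert s.mean_intraburst_rate == pytest.approx(
            (1 / 0.075 + 1 / 0.06) / 2)
        # 13.33 Hz and 16.67 Hz average to 15 Hz
        assert (13.33 + 16.67) / 2 == pytest.approx(15.0, abs=0.01)

    def test_no_bursts_undefined_rate(self):
        tr = SpikeTrain(np.arange(5) * 0.5, 3.0)
        s = burst_stats(tr, [])
        assert np.isnan(s.mean_intraburst_rate) and s.sfb == 0
        assert not s.is_bursty


class TestPauseThreshold:
    def test_zero_iqr(self):
        assert pause_threshold([0.2] * 10) == pytest.approx(0.2)

    def test_formula_against_quantiles(self, rng):
        isis = rng.exponential(0.3, size=101)
        q1, q3 = np.quantile(isis, [0.25, 0.75])
        assert pause_threshold(isis) == pytest.approx(q3 + 3 * (q3 - q1))

    def test_known_quartiles(self):
        # sample engineered so q1 = 0.1 and q3 = 0.2 under type-7 quantiles
        isis = [0.1, 0.1, 0.1, 0.2, 0.2, 0.2]
        assert pause_threshold(isis) == pytest.approx(0.5)

    def test_at_least_q3_and_too_few(self, rng):
        isis = rng.uniform(0.05, 1.0, size=50)
        assert pause_threshold(isis) >= np.quantile(isis, 0.75)
        assert np.isnan(pause_threshold([0.1, 0.2, 0.3]))


class TestDetectPauses:
    def test_single_inserted_gap(self):
        t = np.concatenate([np.arange(0, 10, 0.2), np.arange(12, 22, 0.2)])
        tr = SpikeTrain(t, 22.0)
        ps = detect_pauses(tr, [], span=22.0)
        assert ps.threshold_pthr == pytest.approx(0.2)
        assert len(ps.pause_isi_indices) == 1
        assert ps.mean_pause_duration == pytest.approx(2.2, abs=1e-6)

    def test_post_burst_gap_excluded(self):
        # burst then a long gap: the gap follows the burst's last spike
        t = np.concatenate([np.arange(0, 10, 0.2),
                            [10.0, 10.05, 10.1],  # burst
                            np.arange(13.0, 20, 0.2)])
        tr = SpikeTrain(t, 20.0)
        bursts = detect_bursts(tr)
        assert len(bursts) == 1
        with_excl = detect_pauses(tr, bursts)
        without = detect_pauses(tr, bursts,
                                PauseCriteria(exclude_post_burst=False))
        assert len(without.pause_isi_indices) \
            == len(with_excl.pause_isi_indices) + 1

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40, deadline=None)
    def test_pause_set_monotone_in_w(self, seed):
        tr = random_train(np.random.default_rng(seed))
        if tr.n_spikes < 5:
            return
        small = detect_pauses(tr, [], PauseCriteria(w_factor=1.5))
        large = detect_pauses(tr, [], PauseCriteria(w_factor=4.0))
        assert set(large.pause_isi_indices) <= set(small.pause_isi_indices)
        for i in large.pause_isi_indices:
            assert tr.isis[i] > large.threshold_pthr
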