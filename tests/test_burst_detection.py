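"""Burst detection on the pooled train, IBIs and superburst grouping."""

from __future__ import annotations

import numpy as np
import pytest

from meaburst import (
    NetworkBurst,
    SpikeTrainSet,
    compute_ibis,
    detect_network_bursts,
    group_superbursts,
    pool_spikes,
)
from meaburst.burst_detection import PooledSpike

from conftest import make_pooled


def brute_force_detect(pooled, isi_thresh=0.1, min_electrodes=5, min_spikes=5):
    """Independent O(n^2) oracle: enumerate maximal sub-threshold runs."""
    n = len(pooled)
    times = [p.time for p in pooled]
    bursts = []
    for i in range(n):
        for j in range(i + 1, n):
            # candidate window [i, j]: every consecutive ISI below threshold
            if all(times[k + 1] - times[k] < isi_thresh for k in range(i, j)):
                left_max = i == 0 or times[i] - times[i - 1] >= isi_thresh
                right_max = j == n - 1 or times[j + 1] - times[j] >= isi_thresh
                if left_max and right_max:
                    member = pooled[i : j + 1]
                    electrodes = {p.electrode_id for p in member}
                    if len(member) >= min_spikes and len(electrodes) >= min_electrodes:
                        bursts.append((times[i], times[j], len(member)))
    return bursts


def random_pooled(rng, n_max=200):
    n = int(rng.integers(2, n_max))
    times = np.sort(rng.exponential(0.08, n).cumsum())
    eids = rng.integers(0, 10, n)
    return make_pooled(times, [f"e{k}" for k in eids])


class TestPooling:
    def test_merge_order(self):
        s = SpikeTrainSet(
            trains={"e1": np.array([0.1, 0.3]), "e2": np.array([0.2])},
            t_start=0.0,
            t_stop=1.0,
        )
        assert pool_spikes(s) == [
            PooledSpike(0.1, "e1"),
            PooledSpike(0.2, "e2"),
            PooledSpike(0.3, "e1"),
        ]

    def test_ties_ordered_by_electrode_id(self):
        s = SpikeTrainSet(
            trains={"e2": np.array([0.2]), "e1": np.array([0.2])},
            t_start=0.0,
            t_stop=1.0,
        )
        assert [p.electrode_id for p in pool_spikes(s)] == ["e1", "e2"]

    def test_conservation(self, rng):
        trains = {f"e{i}": np.sort(rng.uniform(0, 10, 30)) for i in range(6)}
        s = SpikeTrainSet(trains=trains, t_start=0.0, t_stop=10.0)
        assert len(pool_spikes(s)) == 180


class TestDetection:
    def test_single_burst_example(self):
        pooled = make_pooled(
            [0.00, 0.05, 0.09, 0.15, 0.21, 1.00], ["a", "b", "c", "d", "e", "a"]
        )
        bursts = detect_network_bursts(pooled)
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.onset, b.offset) == (0.00, 0.21)
        assert b.n_spikes == 5 and len(b.electrodes) == 5

    def test_min_electrodes_rule(self):
        pooled = make_pooled(
            [0.0, 0.05, 0.10, 0.15, 0.20], ["a", "b", "c", "d", "a"]
        )
        assert detect_network_bursts(pooled) == []

    def test_min_spikes_rule(self):
        pooled = make_pooled([0.0, 0.05, 0.10, 0.15], ["a", "b", "c", "d"])
        assert detect_network_bursts(pooled) == []

    def test_no_sub_threshold_isi_no_burst(self):
        pooled = make_pooled(np.arange(10) * 0.2, [f"e{i}" for i in range(10)])
        assert detect_network_bursts(pooled) == []

    def test_isi_exactly_at_threshold_terminates(self):
        # ISI = 0.1 exactly must not open nor continue a burst
        pooled = make_pooled(
            [0.0, 0.1, 0.2, 0.3, 0.4], ["a", "b", "c", "d", "e"]
        )
        assert detect_network_bursts(pooled) == []

    def test_unsorted_input_rejected(self):
        pooled = make_pooled([0.2, 0.1], ["a", "b"])
        with pytest.raises(ValueError, match="sorted"):
            detect_network_bursts(pooled)

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(300):
            pooled = random_pooled(rng)
            got = [
                (b.onset, b.offset, b.n_spikes)
                for b in detect_network_bursts(pooled)
            ]
            assert got == brute_force_detect(pooled)

    def test_bursts_disjoint_ordered_and_subset(self, rng):
        pooled = random_pooled(rng, n_max=500)
        bursts = detect_network_bursts(pooled)
        prev_end = -np.inf
        all_spikes = set(pooled)
        for b in bursts:
            assert b.onset > prev_end
            prev_end = b.offset
            assert set(b.spikes) <= all_spikes

    def test_raising_threshold_never_loses_burst_spikes(self, rng):
        pooled = random_pooled(rng, n_max=400)
        counts = []
        for thresh in (0.02, 0.05, 0.1, 0.2, 0.5):
            bursts = detect_network_bursts(pooled, isi_thresh=thresh)
            counts.append(sum(b.n_spikes for b in bursts))
        assert counts == sorted(counts)


def _burst(onset, offset, n_el=5):
    spikes = tuple(
        PooledSpike(t, f"e{i}")
        for i, t in enumerate(np.linspace(onset, offset, n_el))
    )
    return NetworkBurst(
        onset=onset,
        offset=offset,
        spikes=spikes,
        electrodes=frozenset(s.electrode_id for s in spikes),
    )


class TestIBIs:
    def test_offset_to_onset_difference(self):
        bursts = [_burst(0.5, 1.0), _burst(8.18, 8.6)]
        np.testing.assert_allclose(compute_ibis(bursts), [7.18])

    def test_fewer_than_two_bursts(self):
        assert compute_ibis([]).size == 0
        assert compute_ibis([_burst(0, 1)]).size == 0

    def test_three_bursts_two_positive_ibis(self):
        bursts = [_burst(0, 1), _burst(3, 4), _burst(10, 11)]
        ibis = compute_ibis(bursts)
        assert ibis.shape == (2,) and np.all(ibis > 0)


class TestSuperbursts:
    def test_two_trains_of_ten(self):
        bursts = [_burst(i * 1.5, i * 1.5 + 0.5) for i in range(10)]
        bursts += [_burst(300 + i * 1.5, 300 + i * 1.5 + 0.5) for i in range(10)]
        sbs = group_superbursts(bursts)
        assert [sb.n_members for sb in sbs] == [10, 10]
        assert sbs[0].start == 0.0 and sbs[1].end == pytest.approx(314.0)

    def test_brute_force_grouping(self, rng):
        onsets = np.sort(rng.uniform(0, 500, 60))
        bursts = [_burst(t, t + 0.2) for t in onsets]
        sbs = group_superbursts(bursts, intra_gap=5.0, inter_gap=50.0)
        # oracle: split wherever the offset->onset gap is >= intra_gap
        groups, cur = [], [bursts[0]]
        for prev, b in zip(bursts, bursts[1:]):
            if b.onset - prev.offset >= 5.0:
                groups.append(cur)
                cur = []
            cur.append(b)
        groups.append(cur)
        assert [sb.n_members for sb in sbs] == [len(g) for g in groups]
        assert sum(sb.n_members for sb in sbs) == len(bursts)

    def test_large_gaps_give_singletons(self):
        bursts = [_burst(i * 100.0, i * 100.0 + 1) for i in range(4)]
        sbs = group_superbursts(bursts)
        assert [sb.n_members for sb in sbs] == [1, 1, 1, 1]

    def test_empty_input(self):
        assert group_superbursts([]) == []

    def test_bad_gap_config(self):
        with pytest.raises(ValueError, match="intra_gap"):
            group_superbursts([], intra_gap=60, inter_gap=10)

    def test_ctrl_preset_recovers_ground_truth_bursts(self, ctrl_recording, ctrl_bursts):
        """Midpoint containment: >=95% of true bursts matched on CTRL data."""
        params, _, truth = ctrl_recording
        _, bursts = ctrl_bursts
        d_nom = params.nominal_burst_duration
        hit = 0
        for onset in truth.burst_onsets:
            mid = onset + d_nom / 2
            if any(b.onset <= mid <= b.offset for b in bursts):
                hit += 1
        assert hit / truth.burst_onsets.size >= 0.95
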