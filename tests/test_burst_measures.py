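"""Rate profiles, phase measures (1/16 of peak), OFR/BF and aggregation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from meaburst import (
    NetworkBurst,
    SpikeTrainSet,
    burst_frequency,
    burst_rate_profile,
    extract_measures,
    normalize_to_ctrl,
    overall_firing_rate,
    summarize_across_cultures,
)
from meaburst.burst_detection import PooledSpike
from meaburst.burst_measures import BurstProfile

from conftest import make_pooled

GAUSS_HALF_WIDTH = math.sqrt(2 * math.log(16))  # phase width of a Gaussian peak


def burst_from_times(times, electrodes=None):
    electrodes = electrodes or [f"e{i}" for i in range(len(times))]
    spikes = tuple(PooledSpike(float(t), e) for t, e in zip(times, electrodes))
    return NetworkBurst(
        onset=float(times[0]),
        offset=float(times[-1]),
        spikes=spikes,
        electrodes=frozenset(electrodes),
    )


class TestProfile:
    def test_single_spike_gives_kernel_at_spike(self):
        b = burst_from_times([2.0])
        p = burst_rate_profile(b, np.array([2.0]), pad=0.5)
        # peak at the spike, profile integrates back to one spike
        assert abs((p.t0 + p.t_peak) - 2.0) <= p.bin_width
        assert np.sum(p.rate) * p.bin_width == pytest.approx(1.0, rel=1e-6)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0.0, 0.1, 50)) + 1.0
        shift = 3.25
        b1 = burst_from_times(times)
        b2 = burst_from_times(times + shift)
        p1 = burst_rate_profile(b1, times)
        p2 = burst_rate_profile(b2, times + shift)
        np.testing.assert_allclose(p1.rate, p2.rate, atol=1e-9)
        assert p2.t0 - p1.t0 == pytest.approx(shift)

    def test_count_conservation(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0.0, 0.3, 200)) + 5.0
        b = burst_from_times(times)
        p = burst_rate_profile(b, times)
        assert np.sum(p.rate) * p.bin_width == pytest.approx(200.0, rel=1e-6)

    def test_mfr_against_dense_convolution_oracle(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0.0, 0.1, 100))
        b = burst_from_times(times)
        p = burst_rate_profile(b, times)
        # oracle: direct dense Gaussian-kernel rate estimate at 10x finer grid
        sd = 15 * 0.001
        grid = np.arange(-1.0, 1.1, 0.0001)
        dense = np.zeros_like(grid)
        for t in times:
            dense += np.exp(-0.5 * ((grid - t) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        assert p.mfr == pytest.approx(dense.max(), rel=0.05)

    def test_empty_burst_rejected(self):
        b = burst_from_times([1.0])
        object.__setattr__(b, "spikes", ())
        with pytest.raises(ValueError, match="empty"):
            burst_rate_profile(b, np.array([]))


def gaussian_profile(sigma=0.05, bin_width=0.001, half_window=1.0):
    t = np.arange(-half_window, half_window + bin_width, bin_width)
    rate = 100.0 * np.exp(-0.5 * (t / sigma) ** 2)
    return BurstProfile(bin_width=bin_width, times=t - t[0], rate=rate, t0=t[0])


class TestPhaseMeasures:
    def test_gaussian_closed_form(self):
        """An isolated Gaussian peak of SD s crosses 1/16 of its maximum at
        s*sqrt(2 ln 16) on either side."""
        sigma = 0.05
        p = gaussian_profile(sigma)
        b = burst_from_times(np.linspace(0.4, 0.6, 10))
        m = extract_measures(p, b)
        expected = sigma * GAUSS_HALF_WIDTH
        assert m.RP == pytest.approx(expected, abs=p.bin_width)
        assert m.FP == pytest.approx(expected, abs=p.bin_width)

    def test_symmetric_profile_has_equal_phases(self):
        p = gaussian_profile(0.02)
        b = burst_from_times([0.5])
        m = extract_measures(p, b)
        assert m.RP == pytest.approx(m.FP, abs=1e-9)

    def test_bl_is_rp_plus_fp_exactly(self, ctrl_bursts):
        pooled, bursts = ctrl_bursts
        for b in bursts[:20]:
            m = extract_measures(burst_rate_profile(b, pooled), b)
            assert m.BL == pytest.approx(m.RP + m.FP, abs=1e-12)
            assert m.MFR_per_electrode == pytest.approx(m.MFR / m.RC, abs=1e-12)
            assert m.BS_per_electrode == pytest.approx(m.BS / m.RC, abs=1e-12)

    def test_size_and_recruitment_counts(self):
        times = np.linspace(0.0, 0.2, 204)
        electrodes = [f"e{i % 27}" for i in range(204)]
        b = burst_from_times(times, electrodes)
        p = burst_rate_profile(b, times)
        m = extract_measures(p, b)
        assert m.BS == 204 and m.RC == 27
        assert m.BS_per_electrode == pytest.approx(204 / 27)

    def test_censoring_flagged_when_threshold_not_crossed(self):
        t = np.arange(0, 1.0, 0.001)
        rate = np.full_like(t, 50.0)
        rate[500] = 60.0
        p = BurstProfile(bin_width=0.001, times=t, rate=rate)
        b = burst_from_times([0.5])
        with pytest.warns(UserWarning, match="censored"):
            m = extract_measures(p, b)
        assert m.censored_rise and m.censored_fall

    def test_mfr_invariant_to_pad(self, ctrl_bursts):
        pooled, bursts = ctrl_bursts
        b = bursts[0]
        p1 = burst_rate_profile(b, pooled, pad=1.0)
        p2 = burst_rate_profile(b, pooled, pad=2.0)
        assert p1.mfr == pytest.approx(p2.mfr, rel=1e-6)


class TestRates:
    def test_overall_firing_rate(self):
        s = SpikeTrainSet(
            trains={"a": np.linspace(0, 299, 600)}, t_start=0.0, t_stop=300.0
        )
        assert overall_firing_rate(s) == pytest.approx(2.0)

    def test_empty_recording_zero_rate(self):
        s = SpikeTrainSet(trains={}, t_start=0.0, t_stop=10.0)
        assert overall_firing_rate(s) == 0.0

    def test_burst_frequency_per_minute(self):
        bursts = [object()] * 30
        assert burst_frequency(bursts, 900.0) == pytest.approx(2.0)
        assert burst_frequency([], 900.0) == 0.0

    def test_hz_to_per_minute_consistency(self):
        # 0.12 bursts/s over 100 s -> 12 bursts -> 7.2 per minute
        assert burst_frequency([object()] * 12, 100.0) == pytest.approx(7.2)

    def test_normalize_to_ctrl(self):
        assert normalize_to_ctrl(2.0, 2.0) == 1.0
        assert normalize_to_ctrl(1.0, 2.0) == 0.5
        np.testing.assert_allclose(
            normalize_to_ctrl(np.array([1.0, 2.0]), 2.0), [0.5, 1.0]
        )
        with pytest.raises(ValueError):
            normalize_to_ctrl(1.0, 0.0)


class TestAggregation:
    def test_single_culture(self):
        s = summarize_across_cultures({"c1": [1.0, 2.0, 3.0]})
        assert s.mean_of_medians == 2.0 and s.sd == 0.0

    def test_two_cultures_hand_computed(self):
        s = summarize_across_cultures({"c1": [1.0], "c2": [3.0]})
        assert s.mean_of_medians == pytest.approx(2.0)
        assert s.sd == pytest.approx(math.sqrt(2))
        assert s.cv == pytest.approx(math.sqrt(2) / 2)

    def test_identical_cultures_zero_cv(self):
        s = summarize_across_cultures({"a": [2.0, 4.0], "b": [2.0, 4.0]})
        assert s.cv == 0.0

    def test_empty_culture_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no bursts"):
            s = summarize_across_cultures({"a": [1.0], "b": []})
        assert list(s.per_culture_medians) == ["a"]

    def test_ctrl_normalization(self):
        s = summarize_across_cultures({"a": [1.0], "b": [3.0]}, ctrl_mean_of_medians=4.0)
        assert s.normalized_to_ctrl == pytest.approx(0.5)
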