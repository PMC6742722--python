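"""Burst rate profiles and per-burst measures.

For each network burst a firing-rate profile is computed by binning the
pooled spike counts (default 1 ms bins) and convolving with a unit-area
Gaussian kernel (default SD of 15 bins, i.e. 15 ms, truncated at +-4 SD).
From the profile the following measures are extracted:

* MFR — maximum firing rate, the peak of the profile (network-summed Hz);
* RP — rising phase, from the last crossing of 1/16 of the MFR before the
  peak up to the peak;
* FP — falling phase, from the peak down to the first crossing of 1/16 of
  the MFR after the peak;
* BL — burst length, RP + FP;
* BS — burst size, spikes per burst;
* RC — recruitment count, electrodes active in the burst;
* MFR and BS per electrode (divided by RC).

Condition-level aggregation follows a median-then-mean scheme: the median
over all bursts of a culture, then mean and sample SD over culture medians,
with the coefficient of variation SD/mean and optional normalization to the
control condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from meaburst.burst_detection import NetworkBurst, PooledSpike
from meaburst.io_spikes import SpikeTrainSet

#: Phase boundaries sit where the profile crosses this fraction of its peak.
PHASE_FRACTION = 1.0 / 16.0


@dataclass
class BurstProfile:
    """Kernel-smoothed firing-rate profile of one burst.

    ``times`` are bin centers relative to the profile window start
    (``t0`` holds the absolute window start); ``rate`` is the smoothed
    network-summed firing rate in Hz.
    """

    bin_width: float
    times: np.ndarray
    rate: np.ndarray
    t0: float = 0.0

    @property
    def mfr(self) -> float:
        """Peak of the profile (maximum firing rate, Hz)."""
        return float(self.rate.max())

    @property
    def t_peak(self) -> float:
        """First time attaining the peak, relative to the window start."""
        return float(self.times[int(np.argmax(self.rate))])


@dataclass(frozen=True)
class BurstMeasures:
    BL: float
    RP: float
    FP: float
    MFR: float
    BS: int
    RC: int
    MFR_per_electrode: float
    BS_per_electrode: float
    censored_rise: bool = False
    censored_fall: bool = False


@dataclass
class ConditionSummary:
    """Median-then-mean aggregate of one measure across cultures."""

    per_culture_medians: dict[str, float]
    mean_of_medians: float
    sd: float
    cv: float
    normalized_to_ctrl: float | None = None


def _spike_times(context: Sequence[PooledSpike] | np.ndarray) -> np.ndarray:
    if isinstance(context, np.ndarray):
        return np.asarray(context, dtype=float)
    return np.fromiter((p.time for p in context), dtype=float, count=len(context))


def burst_rate_profile(
    b: NetworkBurst,
    context: Sequence[PooledSpike] | np.ndarray,
    bin_width: float = 0.001,
    kernel_sd_bins: float = 15.0,
    pad: float = 1.0,
) -> BurstProfile:
    """Smoothed firing-rate profile of burst ``b`` within its context train.

    Spikes in ``[onset - pad, offset + pad]`` are binned at ``bin_width``
    and convolved with a unit-area Gaussian kernel of SD ``kernel_sd_bins``
    bins, truncated at +-4 SD; edges are handled by reflection so the
    smoothed counts conserve the windowed spike count.  ``rate`` is the
    smoothed count divided by the bin width.
    """
    if b.n_spikes == 0:
        raise ValueError("empty burst")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    times = _spike_times(context)
    lo = b.onset - pad
    hi = b.offset + pad
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    in_win = times[(times >= lo) & (times <= edges[-1])]
    counts, _ = np.histogram(in_win, bins=edges)
    smoothed = gaussian_filter1d(
        counts.astype(float), sigma=kernel_sd_bins, mode="reflect", truncate=4.0
    )
    centers = (edges[:-1] + edges[1:]) / 2.0 - lo
    return BurstProfile(
        bin_width=bin_width, times=centers, rate=smoothed / bin_width, t0=lo
    )


def _cross_backward(
    times: np.ndarray, rate: np.ndarray, i_peak: int, thr: float, bin_width: float
) -> tuple[float, bool]:
    """Latest time <= t_peak where the rate is at or below ``thr``."""
    idx = np.nonzero(rate[: i_peak + 1] <= thr)[0]
    if idx.size == 0:
        return float(times[0]), True
    i = int(idx[-1])
    if i == i_peak:
        return float(times[i]), False
    # linear interpolation between bins i (<= thr) and i+1 (> thr)
    r0, r1 = rate[i], rate[i + 1]
    frac = 0.0 if r1 == r0 else (thr - r0) / (r1 - r0)
    return float(times[i] + frac * bin_width), False


def _cross_forward(
    times: np.ndarray, rate: np.ndarray, i_peak: int, thr: float, bin_width: float
) -> tuple[float, bool]:
    """Earliest time >= t_peak where the rate is at or below ``thr``."""
    rel = np.nonzero(rate[i_peak:] <= thr)[0]
    if rel.size == 0:
        return float(times[-1]), True
    i = i_peak + int(rel[0])
    if i == i_peak:
        return float(times[i]), False
    r0, r1 = rate[i - 1], rate[i]  # r0 > thr >= r1
    frac = 0.0 if r1 == r0 else (r0 - thr) / (r0 - r1)
    return float(times[i - 1] + frac * bin_width), False


def extract_measures(p: BurstProfile, b: NetworkBurst) -> BurstMeasures:
    """Extract phase and size measures from a burst profile.

    The rising phase starts at the latest time before the peak where the
    rate is at 1/16 of the MFR (backward scan with linear interpolation
    between bins) and the falling phase ends at the earliest such time after
    the peak.  If a crossing never occurs inside the padded window the
    boundary is used and the side is flagged censored.
    """
    rate = np.asarray(p.rate, dtype=float)
    times = np.asarray(p.times, dtype=float)
    i_peak = int(np.argmax(rate))  # first-attained maximum breaks ties
    mfr = float(rate[i_peak])
    thr = PHASE_FRACTION * mfr
    t_rise, cens_r = _cross_backward(times, rate, i_peak, thr, p.bin_width)
    t_fall, cens_f = _cross_forward(times, rate, i_peak, thr, p.bin_width)
    if cens_r or cens_f:
        warnings.warn(
            "profile does not fall below 1/16 of peak inside the padded window; "
            "phase measure censored at the boundary",
            stacklevel=2,
        )
    rp = float(times[i_peak]) - t_rise
    fp = t_fall - float(times[i_peak])
    bs = b.n_spikes
    rc = len(b.electrodes)
    return BurstMeasures(
        BL=rp + fp,
        RP=rp,
        FP=fp,
        MFR=mfr,
        BS=bs,
        RC=rc,
        MFR_per_electrode=mfr / rc,
        BS_per_electrode=bs / rc,
        censored_rise=cens_r,
        censored_fall=cens_f,
    )


def overall_firing_rate(s: SpikeTrainSet) -> float:
    """Total spikes divided by the duration of the analyzed period (Hz)."""
    if s.duration <= 0:
        raise ValueError("duration must be > 0")
    return s.n_spikes / s.duration


def burst_frequency(bursts: Sequence[NetworkBurst], duration: float) -> float:
    """Network bursts per minute."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return len(bursts) / (duration / 60.0)


def normalize_to_ctrl(value, ctrl_value):
    """Divide a measure (scalar or array) by its control-condition value."""
    ctrl = np.asarray(ctrl_value, dtype=float)
    if np.any(ctrl == 0):
        raise ValueError("control value must be nonzero")
    out = np.asarray(value, dtype=float) / ctrl
    return float(out) if out.ndim == 0 else out


def summarize_across_cultures(
    per_culture: Mapping[str, Sequence[float]],
    ctrl_mean_of_medians: float | None = None,
) -> ConditionSummary:
    """Median per culture, then mean and sample SD across culture medians.

    Cultures with no bursts are excluded with a warning.  The coefficient of
    variation is SD / mean; with a single culture the SD is 0.
    """
    medians: dict[str, float] = {}
    for cid, values in per_culture.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            warnings.warn(f"culture {cid!r} has no bursts; excluded", stacklevel=2)
            continue
        medians[str(cid)] = float(np.median(vals))
    if not medians:
        raise ValueError("no culture with at least one burst")
    m = np.array(list(medians.values()))
    mean = float(m.mean())
    sd = float(m.std(ddof=1)) if m.size > 1 else 0.0
    cv = sd / mean if mean != 0 else float("nan")
    normalized = None
    if ctrl_mean_of_medians is not None:
        normalized = normalize_to_ctrl(mean, ctrl_mean_of_medians)
    return ConditionSummary(
        per_culture_medians=medians,
        mean_of_medians=mean,
        sd=sd,
        cv=cv,
        normalized_to_ctrl=normalized,
    )
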