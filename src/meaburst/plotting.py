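"""Minimal plotting helpers (burst profile, CC distribution, recruitment)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from meaburst.burst_measures import PHASE_FRACTION, BurstProfile
from meaburst.recruitment import RecruitmentCurve
from meaburst.similarity import SimilarityResult


def plot_profile(p: BurstProfile, ax=None):
    """Burst rate profile with the peak and the 1/16-of-peak level."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(p.times, p.rate, lw=1)
    ax.axhline(PHASE_FRACTION * p.mfr, ls="--", c="gray", lw=0.8)
    ax.axvline(p.t_peak, ls=":", c="k", lw=0.8)
    ax.set_xlabel("time in profile window (s)")
    ax.set_ylabel("network firing rate (Hz)")
    return ax


def plot_recruitment(curves: dict[str, RecruitmentCurve], ax=None):
    """Mean cumulative recruited electrodes vs time since burst onset."""
    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        ax.plot(c.times, c.mean_cumulative, label=label, lw=1)
    ax.set_xlabel("time since burst onset (s)")
    ax.set_ylabel("mean recruited electrodes")
    ax.legend()
    return ax


def plot_cc_distribution(res: SimilarityResult, ax=None):
    """Distribution of pairwise pattern correlation coefficients."""
    if ax is None:
        _, ax = plt.subplots()
    centers = (res.bin_edges[:-1] + res.bin_edges[1:]) / 2
    ax.bar(centers, res.distribution, width=np.diff(res.bin_edges), align="center")
    ax.set_xlabel("correlation coefficient")
    ax.set_ylabel("fraction of burst pairs")
    return ax
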