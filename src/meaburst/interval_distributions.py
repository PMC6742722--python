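"""ISI and IBI distributions on logarithmic bins.

Within-burst interspike intervals (ISIs) and interburst intervals (IBIs)
are histogrammed over powers-of-ten bin edges ``10**i``:

* ISI grid: i in {-10, -9.8, ..., 6} (step 0.2);
* IBI grid: i in {0, 0.05, ..., 5} (step 0.05).

The IBI sequence is first smoothed in occurrence order with a length-5
Gaussian window of SD 0.65 (window-index units, edge-renormalized weights)
before histogramming; this pre-smoothing of the raw interval sequence is
unusual but deliberately retained.  Intervals falling outside the stated
grid (e.g. sub-second IBIs under gradual AMPA-receptor blockade) are counted
as out-of-range rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from meaburst.burst_detection import NetworkBurst, compute_ibis

#: Default log10-exponent grids (start, step, end).
ISI_GRID = (-10.0, 0.2, 6.0)
IBI_GRID = (0.0, 0.05, 5.0)


@dataclass
class LogHistogram:
    """Counts and fractions over ``10**i`` bin edges.

    ``fractions`` normalizes the in-range counts; values outside the grid
    are tallied in ``n_out_of_range``.  ``empty`` flags a histogram with no
    in-range values (fractions undefined, all-NaN).
    """

    exponents: np.ndarray
    edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    n_out_of_range: int

    @property
    def empty(self) -> bool:
        return int(self.counts.sum()) == 0


def log_exponent_grid(i_start: float, i_step: float, i_end: float) -> np.ndarray:
    """Exponent grid generated by count to avoid floating-point drift."""
    if not i_start < i_end:
        raise ValueError("i_start must be < i_end")
    if i_step <= 0:
        raise ValueError("i_step must be > 0")
    n_edges = int(round((i_end - i_start) / i_step)) + 1
    return i_start + i_step * np.arange(n_edges)


def isi_within_bursts(bursts: Sequence[NetworkBurst]) -> np.ndarray:
    """ISIs between consecutive member spikes of each burst, concatenated.

    Intervals never span burst boundaries; simultaneous spikes contribute
    zero-length ISIs.
    """
    pieces = [np.diff(b.times) for b in bursts if b.n_spikes >= 2]
    if not pieces:
        return np.empty(0)
    return np.concatenate(pieces)


def log_histogram(
    values: Sequence[float] | np.ndarray,
    i_start: float,
    i_step: float,
    i_end: float,
) -> LogHistogram:
    """Histogram positive durations over ``10**i`` edges.

    Bins are left-closed right-open; a value exactly at the final edge is
    assigned to the last bin.  Non-positive values cannot sit on a log grid
    and are routed to the out-of-range tally with a warning.
    """
    exps = log_exponent_grid(i_start, i_step, i_end)
    edges = np.power(10.0, exps)
    vals = np.asarray(values, dtype=float).ravel()
    nonpos = vals <= 0
    if np.any(nonpos):
        warnings.warn(
            f"{int(nonpos.sum())} non-positive interval(s) routed out-of-range",
            stacklevel=2,
        )
    pos = vals[~nonpos]
    in_range = (pos >= edges[0]) & (pos <= edges[-1])
    idx = np.searchsorted(edges, pos[in_range], side="right") - 1
    idx = np.minimum(idx, edges.size - 2)  # value at the last edge -> last bin
    counts = np.bincount(idx, minlength=edges.size - 1)
    total = counts.sum()
    if total > 0:
        fractions = counts / total
    else:
        fractions = np.full(counts.shape, np.nan)
    n_out = int(nonpos.sum()) + int((~in_range).sum())
    return LogHistogram(
        exponents=exps,
        edges=edges,
        counts=counts,
        fractions=fractions,
        n_out_of_range=n_out,
    )


def smooth_sequence_gaussian(
    values: Sequence[float] | np.ndarray,
    window: int = 5,
    sd: float = 0.65,
) -> np.ndarray:
    """Moving Gaussian-weighted average of an occurrence-ordered sequence.

    The window has ``window`` taps with weights ``exp(-0.5 (k/sd)**2)`` for
    integer offsets k, renormalized to unit sum; at the edges the window is
    clipped and the remaining weights renormalized, so a constant sequence
    is unchanged.  Output length equals input length.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    vals = np.asarray(values, dtype=float).ravel()
    n = vals.size
    if n == 0:
        return vals.copy()
    if window > n:
        warnings.warn("window longer than sequence; returning input", stacklevel=2)
        return vals.copy()
    half = window // 2
    offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / sd) ** 2)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        ww = w[lo - i + half : hi - i + half]
        out[i] = float(np.dot(ww, vals[lo:hi]) / ww.sum())
    return out


def ibi_distribution(
    bursts: Sequence[NetworkBurst],
    window: int = 5,
    sd: float = 0.65,
    grid: tuple[float, float, float] = IBI_GRID,
) -> LogHistogram:
    """IBI distribution: Gaussian pre-smoothing, then the log histogram."""
    ibis = compute_ibis(bursts)
    if ibis.size == 0:
        exps = log_exponent_grid(*grid)
        nbins = exps.size - 1
        return LogHistogram(
            exponents=exps,
            edges=np.power(10.0, exps),
            counts=np.zeros(nbins, dtype=int),
            fractions=np.full(nbins, np.nan),
            n_out_of_range=0,
        )
    smoothed = smooth_sequence_gaussian(ibis, window=window, sd=sd)
    return log_histogram(smoothed, *grid)


def isi_distribution(
    bursts: Sequence[NetworkBurst],
    grid: tuple[float, float, float] = ISI_GRID,
) -> LogHistogram:
    """Within-burst ISI distribution on the log grid (no pre-smoothing)."""
    return log_histogram(isi_within_bursts(bursts), *grid)


def mean_distribution(histograms: Sequence[LogHistogram]) -> np.ndarray:
    """Condition-level mean: unweighted average of per-culture fractions."""
    if not histograms:
        raise ValueError("need at least one histogram")
    fracs = [h.fractions for h in histograms if not h.empty]
    if not fracs:
        raise ValueError("all histograms are empty")
    shape = fracs[0].shape
    if any(f.shape != shape for f in fracs):
        raise ValueError("histograms must share the same grid")
    return np.mean(np.vstack(fracs), axis=0)
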