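"""Spatio-temporal pattern similarity between network bursts.

Each burst is summarized by its pattern matrix: the antisymmetric matrix of
pairwise differences of per-electrode first-spike times within the burst
(entries defined only where both electrodes participated).  The similarity
of two bursts is the Pearson correlation coefficient (CC) of their pattern
matrices over the upper-triangle entries defined in both — CCs near one
indicate repeated spatio-temporal activation patterns, near minus one
reversed activation orders, near zero unrelated patterns.  Adding a constant
to all of one burst's latencies leaves the CC unchanged (only differences
enter).

Because non-participating electrodes leave undefined entries, each pair of
bursts is compared on the intersection of its defined pairs with a
minimum-overlap guard, and pairs with too little overlap or zero variance
are flagged undefined rather than reported as a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from meaburst.burst_detection import NetworkBurst
from meaburst.recruitment import first_spike_latencies


@dataclass
class PatternMatrix:
    """Pairwise first-spike-time differences of one burst.

    ``D[i, j] = t_first(i) - t_first(j)`` over a fixed electrode order;
    ``defined_mask[i, j]`` is True where both electrodes participated.
    """

    electrodes: tuple[str, ...]
    D: np.ndarray
    defined_mask: np.ndarray


@dataclass
class SimilarityResult:
    cc_matrix: np.ndarray
    cc_values: np.ndarray
    bin_edges: np.ndarray
    distribution: np.ndarray


def pattern_matrix(b: NetworkBurst, electrode_order: Sequence[str]) -> PatternMatrix:
    """Pattern matrix of burst ``b`` over a fixed electrode order."""
    order = tuple(electrode_order)
    lat = first_spike_latencies(b)
    participating = [e for e in order if e in lat]
    if len(participating) < 2:
        raise ValueError("burst has fewer than 2 participating electrodes")
    n = len(order)
    t = np.full(n, np.nan)
    for i, e in enumerate(order):
        if e in lat:
            t[i] = lat[e]
    D = t[:, None] - t[None, :]
    mask = ~np.isnan(D)
    D = np.where(mask, D, 0.0)
    return PatternMatrix(electrodes=order, D=D, defined_mask=mask)


def pattern_cc(
    A: PatternMatrix, B: PatternMatrix, min_common_pairs: int = 10
) -> float | None:
    """Pearson CC of two pattern matrices over common upper-triangle entries.

    Returns ``None`` (undefined) when fewer than ``min_common_pairs``
    entries are defined in both matrices or either side has zero variance.
    """
    if A.electrodes != B.electrodes:
        raise ValueError("pattern matrices use different electrode orders")
    n = len(A.electrodes)
    iu = np.triu_indices(n, k=1)
    common = A.defined_mask[iu] & B.defined_mask[iu]
    if int(common.sum()) < min_common_pairs:
        return None
    x = A.D[iu][common]
    y = B.D[iu][common]
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0:
        return None
    return float((sx @ sy) / denom)


def cc_analysis(
    bursts: Sequence[NetworkBurst],
    electrode_order: Sequence[str],
    min_common_pairs: int = 10,
    bin_width: float = 0.05,
) -> SimilarityResult:
    """All pairwise CCs between bursts plus their distribution on [-1, 1].

    The CC matrix is symmetric with unit diagonal where defined (NaN marks
    undefined entries); the distribution is over the defined upper-triangle
    values, binned at ``bin_width``.
    """
    if len(bursts) < 2:
        raise ValueError("need at least 2 bursts")
    mats = [pattern_matrix(b, electrode_order) for b in bursts]
    n = len(mats)
    cc = np.full((n, n), np.nan)
    values: list[float] = []
    for i in range(n):
        self_cc = pattern_cc(mats[i], mats[i], min_common_pairs)
        cc[i, i] = np.nan if self_cc is None else 1.0
        for j in range(i + 1, n):
            c = pattern_cc(mats[i], mats[j], min_common_pairs)
            if c is not None:
                cc[i, j] = cc[j, i] = c
                values.append(c)
    if not values:
        raise ValueError("all burst pairs are undefined")
    vals = np.array(values)
    n_bins = int(round(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.clip(vals, -1.0, 1.0), bins=edges)
    return SimilarityResult(
        cc_matrix=cc,
        cc_values=vals,
        bin_edges=edges,
        distribution=counts / counts.sum(),
    )
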