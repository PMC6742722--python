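"""Network-burst detection on the pooled spike train.

A network burst (NB) is a brief network-wide episode of intense spiking.
Detection follows an interspike-interval rule on the spike train pooled over
all electrodes: the first pooled ISI below the threshold (default 100 ms)
opens a burst at the earlier spike of that pair, and the first ISI at or
above the threshold closes it at the last spike before the gap.  Candidate
bursts must contain at least ``min_spikes`` spikes and engage at least
``min_electrodes`` distinct electrodes; candidates failing either minimum are
discarded entirely (their spikes return to background).

The interburst interval (IBI) is the time from one burst's last spike to the
next burst's first spike.  Superbursts (SBs) — minutes-long trains of many
NBs separated by long silences, prominent under gradual AMPA-receptor
blockade — are grouped from the detected burst sequence by a gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from meaburst.io_spikes import SpikeTrainSet


class PooledSpike(NamedTuple):
    """A spike in the pooled, time-sorted network train."""

    time: float
    electrode_id: str


@dataclass(frozen=True)
class NetworkBurst:
    """One detected network burst.

    ``onset``/``offset`` are the times of the first and last member spikes;
    ``electrodes`` is the set of electrode ids active during the burst.
    """

    onset: float
    offset: float
    spikes: tuple[PooledSpike, ...]
    electrodes: frozenset[str]

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError("offset must be >= onset")

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)

    @property
    def times(self) -> np.ndarray:
        return np.fromiter((s.time for s in self.spikes), dtype=float)


@dataclass(frozen=True)
class SuperBurst:
    """A train of consecutive network bursts separated by short gaps."""

    member_bursts: tuple[NetworkBurst, ...]

    @property
    def start(self) -> float:
        return self.member_bursts[0].onset

    @property
    def end(self) -> float:
        return self.member_bursts[-1].offset

    @property
    def n_members(self) -> int:
        return len(self.member_bursts)


def pool_spikes(s: SpikeTrainSet) -> list[PooledSpike]:
    """Merge all electrode trains into one time-sorted network train.

    Simultaneous spikes are ordered by electrode id (stable tie rule).
    """
    times: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for eid in sorted(s.trains):
        t = s.trains[eid]
        if t.size:
            times.append(t)
            ids.append(np.full(t.size, eid, dtype=object))
    if not times:
        return []
    all_t = np.concatenate(times)
    all_e = np.concatenate(ids)
    # mergesort is stable; electrode blocks are already id-sorted, so ties
    # in time keep id order.
    order = np.argsort(all_t, kind="mergesort")
    return [PooledSpike(float(t), str(e)) for t, e in zip(all_t[order], all_e[order])]


def detect_network_bursts(
    pooled: Sequence[PooledSpike],
    isi_thresh: float = 0.100,
    min_electrodes: int = 5,
    min_spikes: int = 5,
) -> list[NetworkBurst]:
    """Detect network bursts from the pooled train by the ISI rule.

    A burst opens at the first spike of the first sub-threshold ISI while
    outside a burst and closes at the last spike before the first ISI at or
    above the threshold (an ISI exactly equal to the threshold terminates and
    does not open; an ISI of zero counts as sub-threshold).  Candidates with
    fewer than ``min_spikes`` spikes or ``min_electrodes`` distinct
    electrodes are dropped.
    """
    times = np.fromiter((p.time for p in pooled), dtype=float, count=len(pooled))
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("pooled spikes must be time-sorted")
    bursts: list[NetworkBurst] = []
    if times.size < 2:
        return bursts
    below = np.diff(times) < isi_thresh
    n = times.size
    i = 0
    while i < n - 1:
        if below[i]:
            start = i
            j = i
            while j < n - 1 and below[j]:
                j += 1
            end = j  # last spike of the run of sub-threshold ISIs
            member = tuple(pooled[start : end + 1])
            electrodes = frozenset(p.electrode_id for p in member)
            if len(member) >= min_spikes and len(electrodes) >= min_electrodes:
                bursts.append(
                    NetworkBurst(
                        onset=member[0].time,
                        offset=member[-1].time,
                        spikes=member,
                        electrodes=electrodes,
                    )
                )
            i = end
        i += 1
    return bursts


def compute_ibis(bursts: Sequence[NetworkBurst]) -> np.ndarray:
    """Interburst intervals: next burst's onset minus this burst's offset."""
    if len(bursts) < 2:
        return np.empty(0)
    onsets = np.array([b.onset for b in bursts[1:]])
    offsets = np.array([b.offset for b in bursts[:-1]])
    return onsets - offsets


def group_superbursts(
    bursts: Sequence[NetworkBurst],
    intra_gap: float = 10.0,
    inter_gap: float = 60.0,
) -> list[SuperBurst]:
    """Group consecutive bursts separated by gaps below ``intra_gap`` into SBs.

    Every burst belongs to exactly one group (singletons allowed);
    ``inter_gap`` is a sanity parameter separating distinct SBs and must
    exceed ``intra_gap``.
    """
    if intra_gap >= inter_gap:
        raise ValueError("intra_gap must be < inter_gap")
    groups: list[SuperBurst] = []
    current: list[NetworkBurst] = []
    for b in bursts:
        if current and b.onset - current[-1].offset >= intra_gap:
            groups.append(SuperBurst(member_bursts=tuple(current)))
            current = []
        current.append(b)
    if current:
        groups.append(SuperBurst(member_bursts=tuple(current)))
    return groups
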