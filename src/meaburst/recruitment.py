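"""Electrode-recruitment curves at burst onset.

For each network burst the first spike time of every participating electrode
is taken relative to the burst onset.  The cumulative number of electrodes
activated by time t, on a fine grid (default 0.1 ms steps over a 0.5 s
window beginning at burst onset), is averaged pointwise over all bursts of a
recording.  The resulting curve quantifies how fast the network recruits
electrodes into a burst; curves may be normalized pointwise to the control
condition.

The analysis window is read as the 0.5 s *following* burst onset (the
recruitment transient completes well within it); the literal alternative —
a window beginning 0.5 s after onset, which would skip the rising phase —
is selectable with ``window_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from meaburst.burst_detection import NetworkBurst


@dataclass
class RecruitmentCurve:
    """Mean cumulative number of recruited electrodes vs time since onset."""

    dt: float
    window: float
    times: np.ndarray
    mean_cumulative: np.ndarray
    n_bursts: int
    normalized: np.ndarray | None = None


def first_spike_latencies(b: NetworkBurst) -> dict[str, float]:
    """First spike time of each participating electrode, relative to onset."""
    latencies: dict[str, float] = {}
    for spike in b.spikes:
        if spike.electrode_id not in latencies:
            latencies[spike.electrode_id] = spike.time - b.onset
    return latencies


def recruitment_curve(
    bursts: Sequence[NetworkBurst],
    window: float = 0.5,
    dt: float = 0.0001,
    window_offset: float = 0.0,
) -> RecruitmentCurve:
    """Average cumulative electrode count on ``[offset, offset + window]``.

    The grid has ``round(window/dt) + 1`` points inclusive of both ends;
    a latency l contributes to every grid point at or after it (latencies
    binned by ``floor(latency/dt)``).
    """
    if not bursts:
        raise ValueError("need at least one burst")
    n_steps = int(round(window / dt))
    times = window_offset + dt * np.arange(n_steps + 1)
    acc = np.zeros(n_steps + 1)
    for b in bursts:
        lat = np.array(sorted(first_spike_latencies(b).values()))
        # cumulative count of latencies <= t for each grid time
        acc += np.searchsorted(lat, times + dt / 2, side="left")
    return RecruitmentCurve(
        dt=dt,
        window=window,
        times=times,
        mean_cumulative=acc / len(bursts),
        n_bursts=len(bursts),
    )


def normalize_curve(c: RecruitmentCurve, ctrl: RecruitmentCurve) -> RecruitmentCurve:
    """Pointwise division by the control curve; undefined points are NaN."""
    if c.times.shape != ctrl.times.shape or not np.allclose(c.times, ctrl.times):
        raise ValueError("recruitment curves are on different grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(
            ctrl.mean_cumulative > 0, c.mean_cumulative / ctrl.mean_cumulative, np.nan
        )
    return RecruitmentCurve(
        dt=c.dt,
        window=c.window,
        times=c.times,
        mean_cumulative=c.mean_cumulative,
        n_bursts=c.n_bursts,
        normalized=norm,
    )
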