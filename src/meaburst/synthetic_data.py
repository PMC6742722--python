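"""Seeded generator of MEA-like spike recordings with ground truth.

The generator emulates the statistical structure of dissociated-culture
recordings so the whole pipeline is testable without recorded data:
recurring network bursts with a fast-rise / slow-decay within-burst rate
envelope, per-electrode recruitment latencies drawn from a small number of
initiation-zone templates, sparse background spiking, and — for the
gradual-AMPAR-blockade regime — superbursts (trains of many slow bursts
separated by minutes of silence).

Model
-----
Burst onsets follow a renewal process whose offset-to-onset gaps are
lognormal.  Within a burst, each electrode joins with probability
``recruit_prob``; a joining electrode fires an inhomogeneous Poisson train
with per-electrode rate ``A * (1 - exp(-t/tau_r)) * exp(-t/tau_f)``
(saturating rise, exponential decay — the simplest shape with independent
rise and decay control, not a biophysical claim), delayed by its
initiation-zone template latency plus an exponential recruitment delay of
scale ``tau_rec`` plus Gaussian jitter.  Background activity is homogeneous
Poisson on every electrode.

All randomness derives from one integer seed; sub-streams are keyed per
burst and electrode so adding electrodes or bursts does not perturb earlier
draws, and a fixed seed reproduces the recording bit-identically.

The named presets encode the qualitative regime orderings of the five
pharmacological conditions (control; acute AMPAR blockade; acute NMDAR
blockade; each followed by GABA_A_R blockade; gradual AMPAR blockade with
superbursts).  The control preset targets the canonical control statistics
of mature cultures: median IBI about 7 s, burst length about 0.37 s with
the falling phase about three times the rising phase, about 27 of 59
electrodes recruited and about 200 spikes per burst, at a burst rate near
0.12 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from meaburst.burst_detection import NetworkBurst
from meaburst.io_spikes import SpikeTrainSet, default_grid


@dataclass(frozen=True)
class SuperburstParams:
    """Superburst hierarchy: trains of bursts separated by long silences."""

    bursts_per_sb_mean: float = 40.0
    intra_gap_mu_log: float = math.log(0.646)
    intra_gap_sd_log: float = 0.4
    inter_gap_mu_log: float = math.log(240.0)
    inter_gap_sd_log: float = 0.3


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic recording.

    Times in seconds, rates in Hz.  ``amplitude`` is the per-electrode peak
    rate scale of the within-burst envelope; ``ibi_mu_log``/``ibi_sd_log``
    parameterize the lognormal offset-to-onset gap law (implied median IBI
    ``exp(ibi_mu_log)``).
    """

    duration: float = 3000.0
    n_electrodes: int = 59
    background_rate: float = 0.03
    ibi_mu_log: float = math.log(7.18)
    ibi_sd_log: float = 0.4
    amplitude: float = 125.0
    tau_r: float = 0.045
    tau_f: float = 0.09
    recruit_prob: float = 0.458
    recruit_delay_scale: float = 0.015
    n_zones: int = 3
    template_spread: float = 0.05
    template_jitter: float = 0.004
    superburst: SuperburstParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.tau_f <= 0:
            raise ValueError("tau_r and tau_f must be > 0")
        if not 0 < self.recruit_prob <= 1:
            raise ValueError("recruit_prob must be in (0, 1]")
        if self.background_rate < 0 or self.amplitude < 0:
            raise ValueError("rates must be >= 0")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")

    # -- envelope helpers --------------------------------------------------

    @property
    def t_peak_envelope(self) -> float:
        """Peak time of the rise*decay envelope."""
        return self.tau_r * math.log1p(self.tau_f / self.tau_r)

    @property
    def envelope_integral(self) -> float:
        """Integral of the unit-amplitude envelope over [0, inf)."""
        return self.tau_f - 1.0 / (1.0 / self.tau_r + 1.0 / self.tau_f)

    @property
    def expected_spikes_per_burst(self) -> float:
        return (
            self.recruit_prob
            * self.n_electrodes
            * self.amplitude
            * self.envelope_integral
        )

    @property
    def nominal_burst_duration(self) -> float:
        """Time at which the expected envelope tail holds about one spike.

        Used to space consecutive burst onsets so that measured IBIs track
        the drawn gaps.
        """
        n = max(self.expected_spikes_per_burst, 2.0)
        return self.t_peak_envelope + self.tau_f * math.log(n)

    @property
    def simulated_burst_support(self) -> float:
        """Envelope support used for spike sampling (truncation negligible)."""
        return self.t_peak_envelope + 10.0 * self.tau_f

    @property
    def implied_median_ibi(self) -> float:
        if self.superburst is not None:
            return math.exp(self.superburst.intra_gap_mu_log)
        return math.exp(self.ibi_mu_log)


@dataclass
class GroundTruth:
    """What the generator actually emitted, for recovery scoring."""

    burst_onsets: np.ndarray
    latencies: list[dict[str, float]]  # per burst: joined electrode -> delay (s)
    zone_of_burst: np.ndarray
    implied_median_ibi: float


_PRESETS: dict[str, SynthParams] = {
    # Control: ~0.12 bursts/s, median IBI ~7 s, BL ~0.37 s with FP ~ 3 RP,
    # ~27/59 electrodes and ~200 spikes per burst.
    "CTRL": SynthParams(),
    # Acute AMPAR blockade (NMDAR-mediated): rare, long, large bursts with
    # longer within-burst ISIs and slower recruitment.
    "NBQX_like": SynthParams(
        background_rate=0.02,
        ibi_mu_log=math.log(60.0),
        ibi_sd_log=0.7,
        amplitude=50.0,
        tau_r=0.12,
        tau_f=0.35,
        recruit_prob=0.45,
        recruit_delay_scale=0.05,
        template_spread=0.12,
        n_zones=2,
    ),
    # Acute NMDAR blockade (AMPAR-mediated): short small bursts on fewer
    # electrodes, fast recruitment, IBIs longer than control.
    "DAP5_like": SynthParams(
        background_rate=0.02,
        ibi_mu_log=math.log(12.0),
        ibi_sd_log=0.6,
        amplitude=170.0,
        tau_r=0.03,
        tau_f=0.045,
        recruit_prob=0.30,
        recruit_delay_scale=0.008,
        template_spread=0.03,
    ),
    # GABA_A_R blockade on top of AMPAR blockade: denser within-burst
    # spiking (shorter ISIs), somewhat shorter bursts, slightly higher
    # burst rate than the AMPAR-blocked condition.
    "NBQX_PTX_like": SynthParams(
        background_rate=0.02,
        ibi_mu_log=math.log(45.0),
        ibi_sd_log=0.7,
        amplitude=110.0,
        tau_r=0.10,
        tau_f=0.22,
        recruit_prob=0.50,
        recruit_delay_scale=0.03,
        template_spread=0.10,
        n_zones=2,
    ),
    # GABA_A_R blockade on top of NMDAR blockade: larger, longer, denser
    # bursts on more electrodes than the NMDAR-blocked condition.
    "DAP5_PTX_like": SynthParams(
        background_rate=0.02,
        ibi_mu_log=math.log(10.0),
        ibi_sd_log=0.6,
        amplitude=300.0,
        tau_r=0.03,
        tau_f=0.07,
        recruit_prob=0.50,
        recruit_delay_scale=0.006,
        template_spread=0.03,
    ),
    # Gradual AMPAR blockade: superbursts of tens of slow bursts separated
    # by minutes-long silences; a single initiation zone gives highly
    # repetitive spatio-temporal patterns.
    "gradual_NBQX_SB": SynthParams(
        duration=1800.0,
        background_rate=0.02,
        amplitude=80.0,
        tau_r=0.08,
        tau_f=0.10,
        recruit_prob=0.45,
        recruit_delay_scale=0.01,
        template_spread=0.06,
        n_zones=1,
        superburst=SuperburstParams(),
    ),
}


def condition_preset(name: str, **overrides) -> SynthParams:
    """Named parameter set for one pharmacological regime.

    Known names: CTRL, NBQX_like, DAP5_like, NBQX_PTX_like, DAP5_PTX_like,
    gradual_NBQX_SB.  Keyword overrides (e.g. ``seed=3, duration=1500``)
    replace preset fields.
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; known: {sorted(_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


def _rng(p: SynthParams, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(p.seed, spawn_key=key))


def _draw_onsets(p: SynthParams) -> tuple[np.ndarray, float]:
    """Burst onset times and the nominal per-burst duration used to space them."""
    d_nom = p.nominal_burst_duration
    rng = _rng(p, 0)
    onsets: list[float] = []
    if p.superburst is None:
        t = float(rng.lognormal(p.ibi_mu_log, p.ibi_sd_log))
        while t + d_nom < p.duration:
            onsets.append(t)
            t += d_nom + float(rng.lognormal(p.ibi_mu_log, p.ibi_sd_log))
    else:
        sb = p.superburst
        t = float(rng.lognormal(sb.intra_gap_mu_log, sb.intra_gap_sd_log))
        while True:
            n_members = max(2, int(rng.poisson(sb.bursts_per_sb_mean)))
            for _ in range(n_members):
                if t + d_nom >= p.duration:
                    break
                onsets.append(t)
                t += d_nom + float(
                    rng.lognormal(sb.intra_gap_mu_log, sb.intra_gap_sd_log)
                )
            if t + d_nom >= p.duration:
                break
            t += float(rng.lognormal(sb.inter_gap_mu_log, sb.inter_gap_sd_log))
            if t + d_nom >= p.duration:
                break
    return np.array(onsets), d_nom


def _envelope_sampler(p: SynthParams, n_grid: int = 2048):
    """Inverse-CDF sampler for the normalized envelope density on its support."""
    t = np.linspace(0.0, p.simulated_burst_support, n_grid)
    shape = (1.0 - np.exp(-t / p.tau_r)) * np.exp(-t / p.tau_f)
    cdf = np.concatenate([[0.0], np.cumsum((shape[1:] + shape[:-1]) / 2.0 * np.diff(t))])
    integral = cdf[-1]
    cdf = cdf / integral

    def sample(rng: np.random.Generator, mean_count: float) -> np.ndarray:
        n = rng.poisson(mean_count)
        if n == 0:
            return np.empty(0)
        return np.interp(rng.random(n), cdf, t)

    return sample, integral


def generate_recording(p: SynthParams) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    Identical parameters (including the seed) give bit-identical output.
    """
    grid = default_grid()
    eids = list(grid.usable_ids)[: p.n_electrodes]
    if len(eids) < p.n_electrodes:
        # more electrodes than the default dish: extend with synthetic ids
        eids += [f"x{i:02d}" for i in range(p.n_electrodes - len(eids))]

    onsets, _ = _draw_onsets(p)
    rng_zone = _rng(p, 1)
    templates = [
        rng_zone.uniform(0.0, p.template_spread, size=p.n_electrodes)
        for _ in range(p.n_zones)
    ]
    zone_of_burst = rng_zone.integers(0, p.n_zones, size=onsets.size)

    sample_env, integral = _envelope_sampler(p)
    mean_count = p.amplitude * integral

    trains: dict[str, list[np.ndarray]] = {e: [] for e in eids}
    latencies: list[dict[str, float]] = []
    for b, onset in enumerate(onsets):
        z = int(zone_of_burst[b])
        burst_lat: dict[str, float] = {}
        for ei, eid in enumerate(eids):
            rng = _rng(p, 2, b, ei)
            if rng.random() >= p.recruit_prob:
                continue
            delay = (
                templates[z][ei]
                + rng.exponential(p.recruit_delay_scale)
                + rng.normal(0.0, p.template_jitter)
            )
            delay = max(delay, 0.0)
            burst_lat[eid] = delay
            spikes = sample_env(rng, mean_count)
            if spikes.size:
                trains[eid].append(np.sort(spikes) + onset + delay)
        latencies.append(burst_lat)

    for ei, eid in enumerate(eids):
        rng = _rng(p, 3, ei)
        n_bg = rng.poisson(p.background_rate * p.duration)
        if n_bg:
            trains[eid].append(rng.uniform(0.0, p.duration, size=n_bg))

    final: dict[str, np.ndarray] = {}
    for eid in eids:
        if trains[eid]:
            t = np.sort(np.concatenate(trains[eid]))
            final[eid] = t[(t >= 0.0) & (t <= p.duration)]
        else:
            final[eid] = np.empty(0)

    sts = SpikeTrainSet(
        trains=final,
        t_start=0.0,
        t_stop=p.duration,
        grid=grid,
        metadata={"culture_id": f"synth-{p.seed}", "condition_label": "synthetic"},
    )
    truth = GroundTruth(
        burst_onsets=onsets,
        latencies=latencies,
        zone_of_burst=np.asarray(zone_of_burst),
        implied_median_ibi=p.implied_median_ibi,
    )
    return sts, truth


def evaluate_recovery(
    truth: GroundTruth,
    detected: Sequence[NetworkBurst],
    measures: Sequence["object"] | None = None,
    onset_tolerance: float = 0.2,
) -> dict[str, float]:
    """Score detected bursts against the generator's ground truth.

    Each true onset is matched greedily (in time order) to the nearest
    unused detected burst whose onset lies within ``onset_tolerance``.
    Reports precision, recall and the relative error of the detected median
    IBI against the generator-implied median; when per-burst ``measures``
    are supplied, median BL/RP/FP and the FP>RP flag are added.
    """
    true_onsets = np.sort(np.asarray(truth.burst_onsets, dtype=float))
    det_onsets = np.array([b.onset for b in detected])
    used = np.zeros(det_onsets.size, dtype=bool)
    matched = 0
    for t in true_onsets:
        if det_onsets.size == 0:
            break
        d = np.abs(det_onsets - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= onset_tolerance:
            used[j] = True
            matched += 1
    recall = matched / true_onsets.size if true_onsets.size else float("nan")
    precision = matched / det_onsets.size if det_onsets.size else float("nan")
    report: dict[str, float] = {
        "n_true": float(true_onsets.size),
        "n_detected": float(det_onsets.size),
        "recall": float(recall),
        "precision": float(precision),
    }
    if len(detected) >= 2:
        from meaburst.burst_detection import compute_ibis

        med = float(np.median(compute_ibis(list(detected))))
        report["median_ibi_detected"] = med
        report["median_ibi_implied"] = truth.implied_median_ibi
        report["ibi_rel_error"] = abs(med - truth.implied_median_ibi) / (
            truth.implied_median_ibi
        )
    if measures:
        rp = float(np.median([m.RP for m in measures]))
        fp = float(np.median([m.FP for m in measures]))
        report["median_rp"] = rp
        report["median_fp"] = fp
        report["median_bl"] = float(np.median([m.BL for m in measures]))
        report["fp_gt_rp"] = float(fp > rp)
    return report
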