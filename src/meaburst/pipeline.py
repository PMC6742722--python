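"""Protocol-level orchestration: from spike tables to result tables.

``run_protocol`` executes the full analysis for a multi-condition session
(control plus antagonist conditions, several cultures each): electrode
filtering, burst detection, per-burst measures, median-then-mean condition
summaries with control normalization, ISI/IBI distributions, recruitment
curves, pattern-similarity analysis and pairwise rank-sum comparisons.  All
outputs are delimited text plus a JSON manifest holding versions, parameters
and per-stage counts, sufficient to reproduce every number in the report.

Inputs per culture are either spike-table files or named synthetic presets;
a declarative YAML config maps onto :class:`RunConfig`.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import meaburst
from meaburst.burst_detection import (
    NetworkBurst,
    compute_ibis,
    detect_network_bursts,
    group_superbursts,
    pool_spikes,
)
from meaburst.burst_measures import (
    BurstMeasures,
    burst_frequency,
    burst_rate_profile,
    extract_measures,
    overall_firing_rate,
    summarize_across_cultures,
)
from meaburst.interval_distributions import (
    IBI_GRID,
    ISI_GRID,
    ibi_distribution,
    isi_distribution,
)
from meaburst.io_spikes import (
    AnalysisWindow,
    SpikeTrainSet,
    apply_analysis_window,
    filter_inactive_electrodes,
    read_spike_table,
)
from meaburst.recruitment import recruitment_curve
from meaburst.similarity import cc_analysis
from meaburst.stats_compare import per_culture_agreement, ranksum
from meaburst.synthetic_data import condition_preset, generate_recording

#: Per-burst measures carried into tables and summaries.
MEASURE_NAMES = ("BL", "RP", "FP", "MFR", "BS", "RC", "MFR_per_electrode", "BS_per_electrode")


@dataclass
class CultureSource:
    """Where one culture/condition recording comes from.

    Either a spike-table ``path`` (with ``dialect`` and the drug-application
    time for windowing) or a synthetic ``preset`` name with a seed.
    """

    path: str | None = None
    dialect: str = "txt"
    drug_application_time: float = 0.0
    preset: str | None = None
    seed: int = 0

    def load(self, window: AnalysisWindow) -> SpikeTrainSet:
        if (self.path is None) == (self.preset is None):
            raise ValueError("source needs exactly one of 'path' or 'preset'")
        if self.path is not None:
            p = Path(self.path)
            if not p.exists():
                raise FileNotFoundError(f"missing input file: {p}")
            s = read_spike_table(p, dialect=self.dialect)
            return apply_analysis_window(s, window, self.drug_application_time)
        params = condition_preset(
            self.preset, seed=self.seed, duration=window.discard + window.analyze
        )
        s, _ = generate_recording(params)
        return apply_analysis_window(s, window, 0.0)


@dataclass
class RunConfig:
    """Declarative configuration of one protocol run."""

    conditions: dict[str, dict[str, CultureSource]]
    protocol_id: int = 1
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    ctrl_condition: str = "CTRL"
    activity_frac: float = 0.09
    isi_thresh: float = 0.100
    min_electrodes: int = 5
    min_spikes: int = 5
    bin_width: float = 0.001
    kernel_sd_bins: float = 15.0
    pad: float = 1.0
    recruit_window: float = 0.5
    recruit_dt: float = 0.0001
    min_common_pairs: int = 10
    sb_intra_gap: float = 10.0
    sb_inter_gap: float = 60.0
    output_dir: str = "meaburst_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        window = AnalysisWindow(**raw.pop("window", {}))
        conditions = {
            cond: {
                str(cid): CultureSource(**src)
                for cid, src in spec["cultures"].items()
            }
            for cond, spec in raw.pop("conditions").items()
        }
        return cls(conditions=conditions, window=window, **raw)


def analyze_recording(
    s: SpikeTrainSet, cfg: RunConfig
) -> dict[str, object]:
    """Run every analysis stage on one windowed recording."""
    out: dict[str, object] = {}
    stage = "filter_electrodes"
    try:
        filtered, report = filter_inactive_electrodes(s, cfg.activity_frac)
        out["filter_report"] = report
        stage = "pool_spikes"
        pooled = pool_spikes(filtered)
        stage = "detect_bursts"
        bursts = detect_network_bursts(
            pooled, cfg.isi_thresh, cfg.min_electrodes, cfg.min_spikes
        )
        out["bursts"] = bursts
        out["superbursts"] = group_superbursts(
            bursts, cfg.sb_intra_gap, cfg.sb_inter_gap
        )
        stage = "burst_measures"
        measures = [
            extract_measures(
                burst_rate_profile(
                    b, pooled, cfg.bin_width, cfg.kernel_sd_bins, cfg.pad
                ),
                b,
            )
            for b in bursts
        ]
        out["measures"] = measures
        out["ofr"] = overall_firing_rate(filtered)
        out["bf_per_min"] = burst_frequency(bursts, filtered.duration)
        out["ibis"] = compute_ibis(bursts)
        stage = "interval_distributions"
        out["isi_hist"] = isi_distribution(bursts)
        out["ibi_hist"] = ibi_distribution(bursts)
        stage = "recruitment"
        out["recruitment"] = (
            recruitment_curve(bursts, cfg.recruit_window, cfg.recruit_dt)
            if bursts
            else None
        )
        stage = "similarity"
        out["similarity"] = (
            cc_analysis(bursts, sorted(filtered.trains), cfg.min_common_pairs)
            if len(bursts) >= 2
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return out


def measures_table(
    results: Mapping[str, Mapping[str, dict]], cfg: RunConfig
) -> pd.DataFrame:
    """One row per burst: culture, condition, onset and all measures."""
    rows = []
    for cond, cultures in results.items():
        for cid, res in cultures.items():
            for b, m in zip(res["bursts"], res["measures"]):
                rows.append(
                    {
                        "culture_id": cid,
                        "condition": cond,
                        "onset_s": b.onset,
                        "BL_s": m.BL,
                        "RP_s": m.RP,
                        "FP_s": m.FP,
                        "MFR_Hz": m.MFR,
                        "BS": m.BS,
                        "RC": m.RC,
                        "BS_per_el": m.BS_per_electrode,
                        "MFR_per_el_Hz": m.MFR_per_electrode,
                    }
                )
    return pd.DataFrame(rows)


def condition_summaries(
    results: Mapping[str, Mapping[str, dict]], cfg: RunConfig
) -> pd.DataFrame:
    """Median-then-mean summaries per condition, normalized to control."""
    rows = []
    ctrl_means: dict[str, float] = {}
    order = [cfg.ctrl_condition] + [
        c for c in results if c != cfg.ctrl_condition
    ]
    for cond in order:
        if cond not in results:
            continue
        for name in MEASURE_NAMES:
            per_culture = {
                cid: [getattr(m, name) for m in res["measures"]]
                for cid, res in results[cond].items()
            }
            try:
                summ = summarize_across_cultures(
                    per_culture, ctrl_means.get(name)
                )
            except ValueError:
                continue
            if cond == cfg.ctrl_condition:
                ctrl_means[name] = summ.mean_of_medians
            rows.append(
                {
                    "condition": cond,
                    "measure": name,
                    "mean_of_medians": summ.mean_of_medians,
                    "sd": summ.sd,
                    "cv": summ.cv,
                    "normalized_to_ctrl": summ.normalized_to_ctrl,
                    "n_cultures": len(summ.per_culture_medians),
                }
            )
    return pd.DataFrame(rows)


def comparison_table(
    results: Mapping[str, Mapping[str, dict]], cfg: RunConfig
) -> pd.DataFrame:
    """Per-culture rank-sum comparisons of every measure between conditions.

    Each non-control condition is compared with the control within every
    culture present in both; the all-cultures-agree flag replicates the
    convention of displaying significance only when every culture's test
    shows it.
    """
    rows = []
    ctrl = results.get(cfg.ctrl_condition, {})
    for cond, cultures in results.items():
        if cond == cfg.ctrl_condition:
            continue
        for name in MEASURE_NAMES:
            per_culture_results = []
            for cid in sorted(set(cultures) & set(ctrl)):
                x = [getattr(m, name) for m in ctrl[cid]["measures"]]
                y = [getattr(m, name) for m in cultures[cid]["measures"]]
                if not x or not y:
                    continue
                r = ranksum(x, y)
                per_culture_results.append((cid, r))
            if not per_culture_results:
                continue
            agree = per_culture_agreement([r for _, r in per_culture_results])
            for cid, r in per_culture_results:
                rows.append(
                    {
                        "measure": name,
                        "condition_A": cfg.ctrl_condition,
                        "condition_B": cond,
                        "culture_id": cid,
                        "p": r.p_two_sided,
                        "stars": r.stars,
                        "method": r.method,
                        "agree_flag": agree,
                    }
                )
    return pd.DataFrame(rows)


def run_protocol(cfg: RunConfig) -> dict[str, object]:
    """Execute the full analysis and write the report bundle.

    Returns the in-memory results; writes measures, summary, comparison,
    distribution and recruitment tables plus ``manifest.json`` into
    ``cfg.output_dir``.  Reruns with the same config are byte-identical.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict[str, dict]] = {}
    manifest: dict[str, object] = {
        "package": "meaburst",
        "version": meaburst.__version__,
        "python": platform.python_version(),
        "protocol_id": cfg.protocol_id,
        "parameters": {
            "window_discard_s": cfg.window.discard,
            "window_analyze_s": cfg.window.analyze,
            "activity_frac": cfg.activity_frac,
            "isi_thresh_s": cfg.isi_thresh,
            "min_electrodes": cfg.min_electrodes,
            "min_spikes": cfg.min_spikes,
            "bin_width_s": cfg.bin_width,
            "kernel_sd_bins": cfg.kernel_sd_bins,
            "pad_s": cfg.pad,
            "recruit_window_s": cfg.recruit_window,
            "recruit_dt_s": cfg.recruit_dt,
            "min_common_pairs": cfg.min_common_pairs,
        },
        "stages": {},
    }
    for cond, cultures in cfg.conditions.items():
        results[cond] = {}
        for cid, source in cultures.items():
            s = source.load(cfg.window)
            res = analyze_recording(s, cfg)
            results[cond][cid] = res
            manifest["stages"][f"{cond}/{cid}"] = {
                "n_spikes_in": s.n_spikes,
                "n_electrodes_kept": res["filter_report"]["n_kept"],
                "electrodes_removed": res["filter_report"]["removed_ids"],
                "n_bursts": len(res["bursts"]),
                "n_superbursts": len(res["superbursts"]),
                "source_seed": source.seed,
                "source_preset": source.preset,
                "source_path": source.path,
            }

    sep = "\t"
    measures_table(results, cfg).to_csv(
        outdir / "burst_measures.tsv", sep=sep, index=False, float_format="%.6g"
    )
    condition_summaries(results, cfg).to_csv(
        outdir / "condition_summaries.tsv", sep=sep, index=False, float_format="%.6g"
    )
    comparison_table(results, cfg).to_csv(
        outdir / "comparisons.tsv", sep=sep, index=False, float_format="%.6g"
    )
    dist_rows = []
    for cond, cultures in results.items():
        for cid, res in cultures.items():
            for kind in ("isi", "ibi"):
                h = res[f"{kind}_hist"]
                for k in range(h.counts.size):
                    dist_rows.append(
                        {
                            "condition": cond,
                            "culture_id": cid,
                            "kind": kind.upper(),
                            "left_edge_s": h.edges[k],
                            "right_edge_s": h.edges[k + 1],
                            "count": int(h.counts[k]),
                            "fraction": h.fractions[k],
                        }
                    )
    pd.DataFrame(dist_rows).to_csv(
        outdir / "interval_distributions.tsv", sep=sep, index=False, float_format="%.6g"
    )
    rec_rows = []
    for cond, cultures in results.items():
        for cid, res in cultures.items():
            c = res["recruitment"]
            if c is None:
                continue
            # store at 10 ms granularity to keep tables small
            step = max(1, int(round(0.01 / c.dt)))
            for k in range(0, c.times.size, step):
                rec_rows.append(
                    {
                        "condition": cond,
                        "culture_id": cid,
                        "t_s": c.times[k],
                        "mean_cumulative": c.mean_cumulative[k],
                    }
                )
    pd.DataFrame(rec_rows).to_csv(
        outdir / "recruitment_curves.tsv", sep=sep, index=False, float_format="%.6g"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


# --------------------------------------------------------------------------
# reproduction of control statistics from a recorded dataset


def control_statistics(
    recordings: Sequence[SpikeTrainSet], cfg: RunConfig | None = None
) -> dict[str, float]:
    """Mean across cultures of per-culture medians of the control measures.

    Takes already-windowed control recordings (one per culture) and returns
    the headline statistics: RP/FP/BL (ms), MFR (Hz), BS (spikes), RC
    (electrodes), median IBI (s) and network-burst frequency (Hz).
    """
    cfg = cfg or RunConfig(conditions={})
    per_culture: dict[str, dict[str, list[float]]] = {
        n: {} for n in ("RP", "FP", "BL", "MFR", "BS", "RC")
    }
    ibi_medians: list[float] = []
    bf_values: list[float] = []
    for k, s in enumerate(recordings):
        cid = str(s.metadata.get("culture_id", k))
        res = analyze_recording(s, cfg)
        for name in per_culture:
            per_culture[name][cid] = [getattr(m, name) for m in res["measures"]]
        if len(res["ibis"]):
            ibi_medians.append(float(np.median(res["ibis"])))
        bf_values.append(res["bf_per_min"] / 60.0)
    stats = {}
    for name, data in per_culture.items():
        stats[name] = summarize_across_cultures(data).mean_of_medians
    return {
        "RP_ms": stats["RP"] * 1e3,
        "FP_ms": stats["FP"] * 1e3,
        "BL_ms": stats["BL"] * 1e3,
        "MFR_Hz": stats["MFR"],
        "BS_spikes": stats["BS"],
        "RC_electrodes": stats["RC"],
        "IBI_s": float(np.mean(ibi_medians)) if ibi_medians else float("nan"),
        "NB_freq_Hz": float(np.mean(bf_values)),
        "n_cultures": float(len(recordings)),
    }


def reproduce_control_statistics(
    data_dir: str | Path, dialect: str = "txt", window: AnalysisWindow | None = None
) -> dict[str, float]:
    """Recompute the control statistics from a directory of recordings.

    ``data_dir`` must hold one spike table per control culture (``*.txt``
    or ``*.h5`` in the package's dialects).  Files are windowed with the
    acute-protocol convention (drop 600 s, analyze 3000 s) when a window is
    given or the recording is long enough, then analyzed with the standard
    parameters (9 % electrode rule, 100 ms ISI threshold, 5/5 minima,
    1 ms bins with a 15-bin kernel SD, 1/16 phase threshold).
    """
    data_dir = Path(data_dir)
    pattern = "*.h5" if dialect == "h5" else "*.txt"
    files = sorted(data_dir.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} spike tables in {data_dir}")
    recordings = []
    for f in files:
        s = read_spike_table(f, dialect=dialect)
        w = window
        if w is None and s.duration >= 3600.0:
            w = AnalysisWindow(discard=600.0, analyze=3000.0)
        if w is not None:
            s = apply_analysis_window(s, w, s.t_start)
        recordings.append(s)
    return control_statistics(recordings)
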