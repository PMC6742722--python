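# meaburst

Network-burst analysis for microelectrode-array (MEA) recordings of
dissociated neuronal cultures.

Cultured cortical networks spontaneously produce *network bursts* (NBs):
brief (~0.5 s) episodes of intense spiking that sweep across the whole
culture, separated by seconds-long quiescent intervals. How excitatory
(AMPA, NMDA) and inhibitory (GABA_A) receptors shape the initiation,
maintenance, propagation and termination of these bursts is studied by
recording multi-unit spike times on planar MEAs (59 usable electrodes on a
6 × 10 grid, 500 µm pitch) under receptor antagonists, and quantifying the
activity with a standard battery of burst measures. `meaburst` implements
that battery as a tested, reusable Python package for experimenters and
modellers who work with per-electrode spike-time data.

## What it computes

* **Burst detection** on the pooled network spike train: an interspike
  interval (ISI) < 100 ms opens a burst, the first ISI ≥ 100 ms closes it;
  candidates need ≥ 5 spikes and ≥ 5 active electrodes. Electrodes firing
  below 9 % of the mean active-electrode rate are excluded first.
* **Burst measures** from a kernel-smoothed rate profile (1 ms bins,
  Gaussian kernel with SD of 15 bins): the peak rate MFR, the rising and
  falling phases RP and FP delimited by the profile crossing MFR/16 on
  either side of the peak, the burst length BL = RP + FP, the burst size
  BS (spikes per burst), the recruitment count RC (active electrodes), and
  MFR and BS per electrode. Condition summaries use per-culture medians,
  then mean ± SD across cultures, with CV = SD/mean and normalization to
  the control condition.
* **Interval distributions**: within-burst ISIs and interburst intervals
  (IBIs, last spike of one burst to first spike of the next) histogrammed
  over powers-of-ten edges 10^i (ISI: i = −10, −9.8, …, 6; IBI: i = 0,
  0.05, …, 5), IBIs pre-smoothed with a length-5 Gaussian window (SD 0.65).
* **Recruitment curves**: the mean cumulative number of electrodes that
  have fired their first burst spike by time t after burst onset, on a
  0.1 ms grid over 0.5 s.
* **Pattern similarity**: per burst, the antisymmetric matrix of pairwise
  differences of per-electrode first-spike times; similarity between two
  bursts is the Pearson correlation of these matrices over common defined
  upper-triangle entries. CC ≈ 1 means repeated spatio-temporal patterns,
  CC ≈ −1 reversed activation order.
* **Statistics**: two-sided Wilcoxon rank-sum tests (exact for small
  tie-free samples) with significance stars, box-plot summaries, and the
  all-cultures-agree reporting convention.
* **Superbursts**: grouping of burst trains (~10² s of closely spaced NBs
  separated by minutes of silence, characteristic of gradual AMPAR
  blockade).
* **Synthetic data**: a seeded generator of MEA-like recordings with
  ground truth, with named presets emulating the five pharmacological
  regimes (control, acute AMPAR/NMDAR blockade, each plus GABA_A_R
  blockade, and gradual AMPAR blockade with superbursts), so the entire
  pipeline is exercisable without recorded data.

## Worked example

```python
import numpy as np
from meaburst import (condition_preset, generate_recording, pool_spikes,
                      detect_network_bursts, burst_rate_profile,
                      extract_measures, compute_ibis, burst_frequency)

params = condition_preset("CTRL", seed=1, duration=1500.0)
spikes, truth = generate_recording(params)
pooled = pool_spikes(spikes)
bursts = detect_network_bursts(pooled)          # 100 ms ISI rule, 5/5 minima
measures = [extract_measures(burst_rate_profile(b, pooled), b) for b in bursts]

print(f"{len(bursts)} network bursts in {spikes.duration:.0f} s "
      f"({burst_frequency(bursts, spikes.duration)/60:.3f} NB/s)")
print(f"median BL = {np.median([m.BL for m in measures])*1e3:.1f} ms "
      f"(RP {np.median([m.RP for m in measures])*1e3:.1f} ms, "
      f"FP {np.median([m.FP for m in measures])*1e3:.1f} ms)")
print(f"median BS = {np.median([m.BS for m in measures]):.0f} spikes on "
      f"{np.median([m.RC for m in measures]):.0f} electrodes")
print(f"median IBI = {np.median(compute_ibis(bursts)):.2f} s")
```

Output:

```
180 network bursts in 1500 s (0.120 NB/s)
median BL = 355.8 ms (RP 92.6 ms, FP 258.0 ms)
median BS = 207 spikes on 27 electrodes
median IBI = 7.03 s
```

The control regime produces bursts about 0.36 s long with an asymmetric
profile (falling phase roughly three times the rising phase), engaging
about 27 of 59 electrodes with ~200 spikes each, recurring every ~7 s —
the canonical behaviour of mature control cultures.

A command-line interface mirrors the library
(`meaburst synth | load | detect | measures | distributions | recruitment |
similarity | compare | run`); `meaburst run config.yaml` executes a full
multi-condition protocol and writes delimited result tables plus a JSON
manifest.

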