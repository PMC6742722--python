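# Methods

This note records how the pipeline's quantities are defined, which choices
were genuinely open, and what the synthetic generator does and does not
emulate.

## Preprocessing

Recordings are windows of per-electrode spike times in seconds. After a
drug application the first 600 s are discarded (transition phase) and the
following 3000 s (acute protocols) or 900 s (gradual protocols) analyzed.
Absolute times are preserved after windowing so conditions of one session
stay aligned; every downstream measure is a time difference and is
unaffected.

Electrodes whose firing rate is below 9 % of the mean rate over electrodes
with any spikes are excluded. The rule is applied **once** (single pass,
not iterated to a fixed point — iterating can cascade exclusions, and the
rule is stated as a single filter). Electrodes with zero spikes enter
neither the mean nor the surviving set. The filter is applied per analyzed
window, not once per session.

## Burst detection

Detection operates on the pooled network spike train (all electrodes
merged, time-sorted, ties broken by electrode id), because the electrode-
count minimum is a separate condition from the ISI rule. A burst opens at
the first spike of the first pooled ISI < 100 ms while outside a burst and
closes at the last spike before the first ISI ≥ 100 ms. Boundary
conventions the verbal rule leaves open: an ISI exactly equal to the
threshold terminates and does not open a burst (strict `<` opens); a
zero ISI counts as sub-threshold; burst onset is the *first* spike of the
opening ISI pair (the alternative second-spike convention shifts results
by at most one ISI). Candidates with fewer than 5 spikes or fewer than 5
distinct electrodes are discarded entirely; their spikes return to
background and are not merged with neighbours.

IBI_k is bursts[k+1].onset − bursts[k].offset. Superbursts are grouped by
a gap rule: consecutive bursts separated by less than `intra_gap` (default
10 s) join one superburst; groups are expected to be separated by at least
`inter_gap` (default 60 s, configuration error if the two are inconsistent).
These two thresholds are implementation choices — the superburst
phenomenon is described (~100 s trains, 3–8 min silences) but no grouping
thresholds are stated; any value of `intra_gap` between the intra-train
gaps (<1 s) and the inter-train silences (minutes) yields the same groups.

## Burst measures

Each burst's rate profile bins the pooled spikes in
[onset − pad, offset + pad] (pad 1 s) at 1 ms and convolves with a
unit-area Gaussian kernel truncated at ±4 SD. The kernel "SD of 15" is
taken as **15 bins at the 1 ms analysis binning**, i.e. 15 ms: at the
10 ms display binning used for profile figures, 15 bins would be 150 ms
and would wipe out the ~89 ms rising phase; analysis binning is therefore
decoupled from display binning. Edges are handled by reflection, so the
smoothed counts conserve the windowed spike count to rounding error.

MFR is the profile maximum (first-attained maximum breaks ties); RP and FP
run from the latest pre-peak and earliest post-peak crossings of MFR/16,
located by backward/forward scan with linear interpolation between bins;
BL = RP + FP exactly. If the profile never falls below MFR/16 inside the
padded window (e.g. bursts inside dense superburst trains, where the 1 s
pad overlaps neighbouring bursts), the boundary is used and the measure is
flagged censored rather than silently truncated. MFR is the network-summed
rate in Hz; with ~200 spikes in ~0.4 s it sits on the 10²–10³ Hz scale.
The per-electrode variants divide MFR and BS by the recruitment count.

Condition aggregation: median over a culture's bursts, then mean and
sample (n−1) SD over culture medians, CV = SD/mean, normalization by the
control mean-of-medians.

## Interval distributions

ISIs are taken between consecutive member spikes within each burst (never
across bursts) and pooled per recording. Histograms use left-closed
right-open bins over 10^i edges generated by count (no cumulative
floating-point drift); a value exactly at the final edge joins the last
bin. Non-positive or out-of-grid values are tallied out-of-range, not
dropped silently — sub-second IBIs under gradual AMPAR blockade fall below
the stated IBI grid start of 10⁰ s.

The IBI sequence is smoothed **before** histogramming with a 5-tap
Gaussian window of SD 0.65 in window-index units, weights renormalized at
the edges. Smoothing the raw interval sequence in occurrence order is an
unusual step, but it is the stated procedure and is kept; smoothing is per
recording (cultures are never concatenated first). Condition-level mean
distributions average per-culture fraction vectors unweighted.

## Recruitment curves

Per burst, each participating electrode's first spike time relative to
burst onset; per grid time t (0.1 ms steps), the count of electrodes with
latency ≤ t; averaged pointwise over bursts. The 0.5 s figure is read as
the **length** of the analysis window starting at burst onset — a window
starting 0.5 s *after* onset would miss the entire rising phase, while
published curves span fractions of a second from onset. The literal
reading remains selectable via `window_offset`.

## Pattern similarity

The pattern matrix D[i,j] is the difference of first-spike times of
electrodes i and j within a burst, defined only where both participated;
it is antisymmetric with zero diagonal. The CC between two bursts is the
Pearson correlation over upper-triangle entries defined in both matrices
(the lower triangle duplicates information and would inflate the sample),
with a minimum-overlap guard of 10 common pairs and an undefined result on
zero variance. Adding a constant to all of one burst's latencies leaves
the CC unchanged. The CC distribution uses 0.05-wide bins on [−1, 1]
(display choice only).

## Statistics

Two-sided Wilcoxon rank-sum throughout; exact enumeration when
n_x + n_y ≤ 16 without ties, otherwise the normal approximation with tie
and continuity corrections. Stars at p < 0.05 / 0.01 / 0.001. Box
summaries default to the Tukey convention (1.5 IQR fences define
outliers, whiskers at the most extreme non-outliers); a `minmax` mode
reproduces the min/max-whisker description, under which no outliers can
exist — the two conventions are mutually inconsistent, so both are
offered and the default documented. Condition comparisons are run per
culture with an all-cultures-agree flag rather than a pooled meta-test;
no multiple-testing correction is applied.

## Synthetic generator

Burst onsets follow a renewal process with lognormal offset-to-onset gaps.
Within a burst, each electrode joins with probability `recruit_prob`; a
joining electrode fires an inhomogeneous Poisson train with per-electrode
rate A·(1 − e^(−t/τ_r))·e^(−t/τ_f), shifted by its initiation-zone
template latency plus an exponential recruitment delay (scale τ_rec) plus
Gaussian jitter; background spiking is homogeneous Poisson. The envelope
family is the simplest shape with independent rise and decay control and
is not a biophysical claim; the lognormal gap law provides the heavy right
tail seen in IBI distributions. All randomness derives from one seed with
sub-streams keyed per burst and electrode, so output is bit-identical for
a fixed seed and unchanged for early electrodes when electrodes are added.

Preset design: the control preset was set from the canonical control
statistics of mature cultures — median IBI ≈ 7.2 s at ~0.12 bursts/s,
BL ≈ 0.37 s with FP ≈ 3 × RP, ~27 of 59 electrodes and ~200 spikes per
burst — via the closed-form envelope peak/integral plus a one-off
simulation check (τ_r 45 ms, τ_f 90 ms, per-electrode amplitude 125 Hz,
recruit probability 0.458, τ_rec 15 ms, background 0.03 Hz per electrode:
sparse quiescent-period firing that keeps spurious sub-100 ms pooled runs
rare). The antagonist presets encode the qualitative regime directions:
AMPAR blockade — rarer, longer, larger bursts with longer within-burst
ISIs and slower recruitment; NMDAR blockade — shorter, smaller bursts on
fewer electrodes with faster recruitment; GABA_A_R blockade overlays —
denser within-burst spiking (shorter ISIs) and, on the NMDAR-blocked
background, larger and longer bursts; gradual AMPAR blockade — superburst
trains of tens of slow bursts (~0.65 s intra-train IBIs, minutes-long
silences) from a single initiation zone.

What the generator does **not** emulate: biophysical receptor kinetics,
spatial wave propagation across the grid (latency templates are spatially
unstructured), electrode cross-talk, spike sorting errors, slow
non-stationarities (development, drug wash-in) and oscillating burst
tails. Passing tests therefore demonstrate correctness of the measures on
data with the stated statistical structure, not fidelity of any
biological claim about recorded cultures.

## Numerical choices and problem sizes

Tolerances: BL = RP + FP asserted to 10⁻¹² s; histogram fractions sum to
1 within 10⁻¹²; CC against direct Pearson within 10⁻¹²; phase measures
against the Gaussian closed form σ·sqrt(2 ln 16) within one bin width.
Text spike tables store times at 0.1 µs, far below the 25 kHz acquisition
resolution (0.04 ms). Test and acceptance problem sizes — 1,000 random
trains for detector-oracle equivalence, 3 seeds × 3000 s for control
parameter recovery, a 20-culture × 3000 s control study for the headline
statistics, 10,000 replicates for rank-sum null calibration — were chosen
to keep each quantity's sampling error well below its assertion margin.

## Known limitations

* Burst phase measures inside dense superburst trains are frequently
  censored because the padded profile window overlaps neighbouring bursts.
* The pooled-train ISI rule can fragment very slow-rising bursts into
  multiple detections; detection precision against ground truth is
  therefore highest in the control regime.
* The exact rank-sum path requires tie-free data; tied samples always use
  the corrected normal approximation, which is approximate for very small
  n with many ties.
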