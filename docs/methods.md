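# Methods

This note documents the models, parameter choices and numerical decisions
behind `sleepspike`, and what the synthetic-data validation does and does
not establish.

## Scope and data model

All analyses operate on three artifact types: sorted spike trains per unit
(seconds from session start, strictly increasing), multi-channel LFP (flat
little-endian float32, channel-major, with a JSON sidecar), and a hypnogram
of half-open `[start, end)` state intervals over NREM/REM/WAKE with brief
microarousals (MA). Half-open intervals are used everywhere so a spike on a
boundary is counted exactly once. Sleep staging itself is out of scope: the
hypnogram is an input.

## Hypnogram post-processing

* Wake/MA bouts shorter than 40 s flanked by sleep, occurring inside NREM
  or at a REM→NREM transition, are relabeled NREM and merged; wake at sleep
  onset/offset is never merged. The operation is idempotent.
* Epochs lasting ≤ 50 s are kept in the timeline but flagged unusable; all
  rate analyses use usable epochs only.
* Extended sleep: maximal sleep runs spanning > 30 min with no internal
  wake bout > 60 s, trimmed to their first/last sleep epoch.
* NREM–REM–NREM triplets: consecutive usable epochs, each > 50 s. An
  intervening excluded (≤ 50 s) epoch does not break consecutiveness,
  because excluded epochs drop out of the analyzed sequence; a switch
  (`tolerate_excluded=False`) restores strict adjacency.

## State preference

Rates are computed in whole 1-s bins laid from each usable epoch start
(trailing fractions < 1 s dropped). The REM-preference index
`(FR_R − FR_N)/(FR_R + FR_N)` is tested against a null obtained by
permuting REM/NREM labels across all pooled bins (preserving label
counts), 1,000 surrogates by default. Percentiles use linear
interpolation; a tie at the threshold is conservatively non-significant.
The shuffle permutes over all pooled bins; a per-session block option would
be a straightforward extension but the pooled variant is the default.

Triplet profiles store all nine thirds (NREM₁, REM, NREM₂ × 3), averaged
over triplets, then z-scored within neuron. Note that z-scoring normalizes
a flat unit's sampling noise to SD 1; flatness shows in the raw thirds, not
in the z-scale.

Cross-session stability is summarized by Spearman correlations of index
vectors over shared units, with bootstrap analyses (resample n = 92 units
with replacement, 5,000 resamples by default) for (i) significance of each
correlation against zero, (ii) differences between temporally adjacent
session pairs, (iii) differences between regions.

## Oscillation detection

All detectors work on z-scored detection traces so they are invariant to
LFP amplitude scaling. Numerical choices the method text leaves open:

* Band-pass filters are zero-phase 4th-order Butterworth (forward-backward).
* Moving RMS is evaluated at every sample with a centered window
  (`round(window × fs)` samples); the 13.3 ms / 20 ms windows are treated
  as sliding, not block-wise.
* Candidate merging is done in the integer sample domain so gap
  comparisons at exactly the merge threshold are unambiguous.
* Z-scoring uses mean/SD over all NREM samples (events included, as in any
  real recording); an empty NREM baseline is an error.
* The spindle transform is a Morlet CWT (ω₀ = 6, Torrence–Compo
  normalization irrelevant because every scale is z-scored), implemented
  in the frequency domain with zero padding; 11 log-spaced center
  frequencies span 9–18 Hz. The > 1.4 z sustain test is a strict run — no
  sub-threshold dips — and candidate runs are clipped to NREM before the
  350 ms test.
* Event "overlap" for cross-channel/shank concatenation means nonempty
  interval intersection; the concatenated event is the union span and
  keeps the strongest contributor's peak.
* Peak time is the argmax of the detection trace inside the event; for
  SWRs, the maximum over contributing channels.
* SWRs are reported in NREM and WAKE (peak-time gating), never REM;
  HFO/cRipple/spindle only in NREM.

The detector parameter tables live in `sleepspike.detect` as frozen
defaults; the stringent robustness set raises the peak thresholds to
z > 5/5/6/3 (SWR/HFO/cRipple/spindle) and is monotone: it can only remove
events.

## Firing-rate modulation

PETHs use 10-ms bins with σ = 50 ms smoothing for ripple-class events and
50-ms bins with σ = 250 ms for spindles, on ±0.5 s / ±2 s lag windows
(chosen to cover the smoothing kernels). FR gain is spikes-in-events over
event time divided by spikes-outside over outside time, within NREM for
sleep oscillations and within WAKE for awake SWRs; "outside" excludes only
the kind under analysis (configurable). Z-scored epoch-rate quantities
(sleep-long trends, first-vs-last NREM comparisons) normalize within unit
over all NREM epochs of all extended-sleep periods — the normalization
population is not fixed by the method description, so this choice is
documented here and applied consistently. Spikes from 0.1 ms before each
2-ms shock pulse to 5 ms after it are censored before any shock analysis;
shock gain is the 0.1-s-bin PSTH peak within the 2-s shock window over the
mean rate in the 20 s before the first CS.

## Coactivity and response indices

Activity is ≥ 1 spike inside the event's `[start, end)` interval (not a
peak-centered window). Pairs with σ = 0 (a unit active in none or all
events, or N = 1) are excluded with a reason. Pair types NN/RR/NR/RN order
cross-regional mixed pairs by the fixed region order vCA1 → PL5 → BLA;
within-region mixed pairs are unordered NR; any NS member makes the pair
"other". Pair analyses prefer included excitatory units and fall back to
all included units when CCG typing yields none (synthetic sessions carry
no waveforms). The NREM-preferring response index is the Pearson r between
the per-event fraction of active NREM-preferring source-region neurons and
the target neuron's in-event rate, over events with at least one active
labeled neuron.

## Cell typing

CCGs are raw pair counts in 0.1-ms bins over ±8 ms (evaluated on ±5 ms, so
σ = 0.5 ms smoothing suffers no edge truncation in the evaluated range);
positive lag means the target fires after the reference. Jitter surrogates
re-draw every spike of both trains independently (uniform ±5 ms), 1,000
times; the 99% global bands are the 99.5th percentile of surrogate maxima
and 0.5th of minima over ±5 ms. Band exceedance is strict. Manual curation
of suspicious connections is approximated by an automatic rule: a
candidate is rejected if its exceedance covers zero lag (±0.4 ms) or is
broader than 6 ms contiguous. The 6 ms width was chosen because a genuine
monosynaptic trough filling the whole [+1, +4] ms window is ~3–4 ms wide
after smoothing, while comodulation artifacts span tens of milliseconds; a
3 ms cut would reject true suppression. The surrogate computation is
vectorized over surrogates by tracking only spike pairs that can reach the
CCG window after jittering.

## Synthetic sessions

The generator emulates what the analyses need and nothing more:

* **Hypnogram:** semi-Markov chain with log-normal dwell times (defaults:
  WAKE median 120 s / σ 0.8, NREM 300 s / 0.5, REM 90 s / 0.4, MA 15 s /
  0.4 truncated below 40 s) and transitions WAKE→NREM;
  NREM→{REM .50, MA .35, WAKE .15}; REM→{NREM .80, WAKE .20}; MA→NREM.
  These make ~2-h sessions usually contain extended sleep, verified
  against a direct Monte-Carlo simulation of the dwell process.
* **Units:** inhomogeneous Poisson with state-constant rates; NREM rate
  log-uniform in 0.5–5 Hz, REM/NREM ratio log-uniform in 0.25–4, WAKE rate
  the geometric mean. Event gains multiply the rate inside injected events
  (thinning for g < 1, superposition for g > 1 — both exact for Poisson
  processes); overlapping events multiply their gains.
* **LFP:** Gaussian 1/f background (spectral exponent 1, frequency-domain
  synthesis, unit SD), 1250 Hz default (the sampling rate is an assumption
  and configurable). Channels: vCA1 superficial+deep on one shank, three
  PL5 channels, one BLA channel. Bursts are injected at 10× the
  band-limited background SD: ripples 150 Hz Gaussian-windowed (50–100 ms)
  with a −8 SD sharp-wave on the superficial−deep difference; HFOs 120 Hz
  (40–80 ms) and cRipples 120 Hz (60–100 ms) with flat-topped Tukey
  envelopes plus a mild central emphasis so the power peak sits at the
  burst center; spindles 12 Hz (0.5–1 s) likewise. cRipple bursts start at
  60 ms because the cRipple criterion requires ≥ 50 ms above threshold — a
  40 ms burst is undetectable by construction. Ripples are injected in
  NREM and WAKE; HFO/cRipple/spindle in NREM only. Events of one kind
  never overlap each other and sit fully inside one state interval.

What the generator does **not** emulate: realistic theta/delta spectra,
EMG, traveling-wave structure, refractory periods, bursting, non-Poisson
count statistics, waveforms/sorting features (so isolation distance and
spike width come from caller-supplied features in real use), or correlated
population dynamics beyond the injected event gains. Passing tests
therefore establish correctness of the estimators under their stated
assumptions, not robustness to every property of in-vivo data.

A note on false positives: on pure Gaussian background, the spindle
thresholds (1.4 z sustained 350 ms, peak 2 z) admit occasional false
events because per-scale wavelet power is exponential-tailed; in full
synthetic (and real) sessions the NREM baseline SD is inflated by the real
events themselves, which suppresses this. Detector precision is therefore
validated on full sessions, not on event-free noise.

## Validation problem sizes

The acceptance checks use: exhaustive hypergeometric enumeration for all
N ≤ 12 plus a 10⁵-shuffle Monte-Carlo at (N, n_A, n_B) = (100, 10, 10);
1,000 state-independent units on ten 2-h hypnograms for type-I calibration
(expected 5%, accepted 3–7%); 200 units per direction at twofold
modulation (0.5 vs 1.0 Hz, 35 min per state) for sensitivity ≥ 95%; one
30-min session per condition with ~100 injected events per kind for
detector recall/precision ≥ 90%; ~500 injected events per gain level for
FR-gain recovery within 10%; 20 pairs per connection type (5-min, 20 Hz
trains) for CCG sensitivity and 400 independent pairs for band
calibration; and a 25-min, 9-unit session run twice for bit-identical
reproducibility. These sizes keep the whole validation within a few
minutes on one core while leaving comfortable statistical margins.

## Known limitations

* The ISI-index and contamination-rate formulas follow the
  window-length-normalized reading of their sources (factors 8/1.5, 49 and
  250); window bounds are half-open in ms.
* The Steel–Dwass reference distribution uses the Studentized range with
  infinite degrees of freedom (the standard large-sample form); exact
  small-sample Steel–Dwass tables are not implemented.
* Spearman p-values are exact (full permutation enumeration) only for
  n ≤ 7; beyond that the t approximation is used.
* The pipeline's quality stage judges inclusion on the metrics available
  in the session; waveform-based criteria apply only when waveforms or
  feature matrices are supplied.
* `classify_preference` assumes exchangeability of 1-s bins under the
  null; strong within-state nonstationarity (e.g., firing trends across
  extended sleep) can inflate its type-I error on real data.
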