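# Methods

## The problem

Focal seizures in pharmacoresistant epilepsy are preceded, tens of minutes
before onset, by measurable changes in cortical activity — and not only in
the clinically identified seizure-onset area. This package implements, as a
reusable pipeline, an analysis showing that the interictal (baseline) and
preictal (pre-seizure) states can be discriminated from intracortical
microelectrode-array (MEA) recordings taken centimeters away from the onset
area, using both subthreshold field potentials and suprathreshold population
spiking. The task is framed as binary classification of short feature
histories, scored by ROC AUC under leave-one-seizure-out cross-validation,
with significance judged against a dependence-preserving permutation null.

Because clinical MEA recordings of this kind are not publicly available, the
package ships a synthetic-data generator that reproduces the *statistical
structure* the analysis assumes — state-dependent spiking rate, band power
and inter-channel coherence — with exact ground truth, so every stage is
testable end to end.

## Signal model and preprocessing

Input is a broadband multichannel recording (channels x samples, kilosample
rates; native HDF5 layout, optional EDF). Three derived streams are
computed, all with 9th-order Butterworth filters applied forward–backward
(zero phase; the effective magnitude response is the square of the design):

* **LFP** — low-pass < 500 Hz, resampled to 2 kS/s.
* **MUA counts** — high-pass > 250 Hz; a spike event is a negative-going
  crossing of −3·SD, counted at its entry sample into 0.5 ms bins, with a
  1 ms lockout so one waveform is counted once. SD is a robust per-channel,
  per-acquisition-file estimate, median(|x|)/0.6745, so sparse large spikes
  do not inflate the threshold.
* **MUA envelope** — the high-passed signal clipped at ±3·SD (de-emphasizing
  near-electrode units in favor of population activation), squared,
  low-pass filtered at 10 Hz, resampled to 2 kS/s, clamped at zero against
  filter ripple.

A per-file z-scoring control (zero mean, unit variance per channel per
40-minute acquisition file) is available to verify that classification does
not ride on slow drifts in mean or scale across the multi-day recording.
Artifact handling is explicit and configurable: samples with |x| > 10·SD
sustained longer than 50 ms mark their interval bad, and feature windows
overlapping a bad interval are excluded.

## Features

All features live on 4-s windows stepped by 2 s. Spectral quantities use
multitaper estimation with a 2 Hz half-bandwidth: time–half-bandwidth
product NW = 8 on the 4-s window, with the full Slepian set of
K = 2·NW − 1 = 15 tapers. Ten frequency bands span 0.3–500 Hz
(0.3–4, 4–8, 8–12, 12–18, 18–25, 25–50, 50–80, 80–150, 150–300,
300–500 Hz).

Four groups per window:

1. **LFP power** — mean PSD per band per channel (bands x channels values).
2. **LFP coherence** — per band, the pairwise magnitude-squared coherence
   matrix (entries in [0,1], diagonal zeroed) is treated as a weighted graph
   adjacency matrix; features are its leading eigenvalue, the leading
   eigenvector (eigenvector centrality, unit norm, sign fixed so the
   largest-magnitude entry is positive), and the mean and variance of the
   upper-triangle entries.
3. **MUA count** — total threshold crossings per channel per window.
4. **MUA correlation** — for the fine count series (0.5 ms bins), the
   coarse count series (100 ms bins) and the envelope: the pairwise
   lagged-correlation-extremum matrix (Pearson correlation at every integer
   lag within ±50 ms, truncating to the common support at each lag; the
   signed value of largest magnitude is kept), then its leading
   eigenvalue/eigenvector.

Numerical conventions worth stating: band averages use every PSD grid
frequency inside the band even where the 2 Hz resolution under-resolves the
lowest band; the ±50 ms lag budget is sub-bin for the 100 ms coarse series,
so its correlation reduces to the zero-lag Pearson; lag ties resolve to the
smallest |lag| with positive lags preferred; eigenvector centrality of
correlation matrices (which may hold negative entries) takes the eigenvector
of the algebraically largest eigenvalue, matrix unmodified; a zero matrix
returns (0, e_1); zero-variance channels zero their rows/columns and are
flagged.

## Labels, samples and cross-validation

Preictal is the interval from 65 to 5 minutes before a seizure onset (the
5-minute guard absorbs onset-time uncertainty); interictal is everything at
least 4 hours from every onset. A seizure whose preictal span contains
another onset, or whose preictal interval is emptied by clipping, is
excluded with a warning.

Classification inputs are histories of n consecutive windows,
n ∈ {2, 3, 5, 10, 15, 25}, spanning 2n + 2 = 6…52 s. Training samples are
oversampled with a one-window stride (consecutive overlap (n−1)/n, i.e.
50%…96%) to soften the class imbalance (about 1:100 at clinical scale);
test samples tile each interval in non-overlapping blocks of n windows —
for both classes, a deliberately symmetric choice (a `test_overlap` toggle
restores overlapping test sampling). Windows are half-open [t, t+4 s) on a
grid anchored at the recording start, and a window must lie fully inside a
labeled interval to inherit its label.

Leave-one-seizure-out folds hold out one seizure's preictal windows together
with the interictal block nearest in time to that seizure (every interictal
window is assigned to its closest seizure anchor, which yields contiguous
blocks). Class weights are w(preictal)/w(interictal) = n_inter/n_pre. A
shuffled-window control reassigns samples to folds at random, deliberately
breaking train/test temporal separation; scores under this scheme bound
how much optimism temporal leakage can buy.

## Classifiers

**LSTM.** Three cells with the standard gated recurrence and a 2-unit dense
softmax readout; parameter count 4·((F+1)·C + C²) + 2C + 2 (1,208 at F=96
inputs, 11,576 at F=960). The state is reset to zero for every sample.
Training minimizes class-weighted cross-entropy with Adadelta (ρ = 0.95,
ε = 1e−7) and 20% dropout on both the input and recurrent contributions
(one mask per sequence, inverted scaling, off at inference). The schedule —
30 epochs, batch 64, early stop after 6 epochs without 1e−4 relative
training-loss improvement — is a package default; no validation split
exists at these data sizes, so early stopping watches the training loss.
The forget-gate bias initializes at 1, other biases at 0, weights
Glorot-uniform. Features are standardized per dimension with training-fold
statistics before entering the network; raw scales span orders of magnitude
(integer counts vs. band powers) and would saturate the gates. The network
is implemented directly in numpy — at three cells it is tiny — with exact
backpropagation-through-time, verified against finite differences.

**Gradient-boosted trees.** XGBoost with depth-3 trees, binary logistic
objective, `scale_pos_weight` equal to the class imbalance ratio, learning
rate 0.3, and 100 rounds by default (no early stopping, for the same
no-validation-set reason; configurable). History windows enter as
time-independent columns. Total-gain importances, normalized to sum to one,
are aggregated per frequency band, per feature group, or per array site
(site scores ranked to a 0–1 scale on the electrode grid).

**Reduced subset.** The importance-ranked subset — LFP power in 50–80 and
80–150 Hz, coherence eigenvectors in 0.3–4 and 300–500 Hz, per-channel MUA
totals, and the envelope-correlation eigenvector — is 6 x n_channels
features and is available as a single unit.

## Statistical assessment

The test statistic is the ROC AUC (concordant-pair probability, ties half).
Because samples are serially dependent, the null is built by *blocked*
label permutation: the training timeline is cut into non-overlapping
10-minute segments, segment labels are shuffled as units, the classifier is
retrained from scratch, and the untouched test set is re-scored; N = 200
replicates by default. The empirical p-value is
p = (1 + #{AUC* > AUC}) / (1 + N) with strict inequality, exactly as
printed; a conservative tie-counting mode exists (off by default) because a
degenerate constant classifier would otherwise earn p = 1/(N+1).
Benjamini–Hochberg FDR is applied over the pooled family of
(recording, feature-group) p-values at target levels 0.05 and 0.01; a
per-recording family is a config option. When a fold's pipeline reports one
AUC per feature group, surrogate AUCs are averaged across folds so the null
matches the reported across-fold mean.

## The synthetic generator

Each channel is a sum of: a pink (1/f power) Gaussian background
band-limited to 0.3–200 Hz; a small flat Gaussian floor in 200–500 Hz;
shared narrowband latent sources per selected band, mixed into every
channel (a one-factor model whose magnitude-squared coherence has the
closed form s²/(s+n)² for shared in-band power s and independent in-band
noise n — used as a recovery oracle in the tests); a bounded
high-frequency noise floor (below); and biphasic ~1 ms spike templates
(0.4 ms negative lobe peaking at −spike_amp·bg_sigma, 0.6 ms positive
lobe) inserted at Poisson times with a 2 ms refractory period, optionally
sharing a slow rate co-fluctuation across channels so count/envelope
correlations carry signal.

The preictal state multiplies the spike rate (x2.0 by default), the latent
variance in two power bands (50–80, 80–150 Hz; x1.5), the mixing
coefficient in two coherence bands (8–12, 18–25 Hz; x1.5), and the shared
rate-fluctuation depth (x1.5). With all multipliers at one the two states
are statistically exchangeable. These effect sizes are free parameters of
the generator, not estimates of real preictal physiology — the source data
give no quantitative effect sizes — and the defaults are the package's
"strong effect" study conditions.

**Why the MUA-band noise floor is amplitude-bounded.** For any Gaussian
process, the rate of −3·SD crossings is set by the Rice formula and is of
order tens per second for a 250 Hz–Nyquist band — noise crossings would
swamp planted spikes and ground-truth counts could never be exact. The
generator therefore gives the detection band a three-sine mixture whose
peak stays below 2.5x its own SD, and keeps Gaussian content in that band
an order of magnitude smaller; the −3·SD threshold is then unreachable by
noise and detected crossings correspond one-to-one to inserted events. This
is a deliberate idealization: real MUA counts include noise crossings, and
the generator trades that realism for exact count ground truth.

Other non-realisms to keep in mind when reading green tests: states switch
instantaneously with no drift between them; spike waveforms are identical
across channels and events; there are no artifacts, electrode dropouts, or
line noise; latent sources are stationary Gaussian rather than transient
oscillations. Passing tests therefore demonstrate that the pipeline
recovers planted structure of the assumed form, not that real seizures are
predictable at any particular accuracy.

## Problem sizes

Default generator geometry is 16 channels at 10 kS/s (scalable to the
clinical 96 channels at 30 kS/s; the pipeline math is dimension-agnostic,
and rates need only keep the 0.5 ms count bin and 2 kS/s derived streams as
integer resamplings). End-to-end runs in the test suite and the acceptance
script use compact recordings at 8 kS/s: four seizures spaced 320 s with a
scaled labeling clock (preictal [onset−65 s, onset−5 s], interictal margin
120 s — minutes mapped to seconds; the state is planted exactly, so the
margin's anti-leakage role keeps large headroom), about 20 minutes of
signal per recording, 5 recording seeds for the strong-effect analysis, 20
seeds for the chance-floor calibration, and 50 surrogates (configurable to
the full 200) for null-calibration checks. The fast feature-timeline path
(Gaussian features with class-dependent means on a 30-min/10-min labeling
cadence) stands in for signal synthesis wherever only the
dataset/model/evaluation layers are under test.

## Known limitations

* No ictal-waveform synthesis and no postictal class; only the
  interictal/preictal contrast the classification uses.
* No spike sorting (deliberately: multiunit counts), no transient-HFO
  detection, no spike–field coherence.
* No continuous no-reset prediction mode and no alarm-latching evaluation
  (sensitivity / false alarms per hour); the statistic is segment-level AUC.
* The history-length hyperparameter is, at clinical data sizes, selected on
  the test folds — an acknowledged optimism shared with the source
  analysis; the package default is 10 windows.
* How interictal hours are apportioned among folds is underdetermined at
  clinical scale; the nearest-anchor block rule is one defensible choice.
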