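# Methods

`cpmosc` implements the oscillatory-marker analysis used to characterize
conditioned pain modulation (CPM) experiments: a synthetic generator of
epoched electrophysiological trials with known injected effects, and the
analysis chain that turns epochs into time–frequency z-maps, event-related
spectral perturbation (ERSP) statistics, baseline spectra, and a
nonparametric inference layer. This note records the model, the parameter
choices, and the design decisions made where the procedure was genuinely
open.

## The synthetic experiment

The generator emulates a sequential CPM protocol: two groups (chronic
pain, CP; pain-free controls, HC) of 17 participants each, three
consecutive blocks (*before*, *during*, *after* the conditioning
stimulus), and ~3-minute blocks of electrical test stimuli delivered at
6–10 s intervals — 22 epochs per block at the ~8 s mean interval. Epochs
span [−2, 6] s around stimulus onset at a default sampling rate of
600 Hz (configurable; all analysis frequencies are ≤ 60 Hz, so desk-scale
runs use 300 Hz without loss).

Each epoch is the sum of:

* **1/f background** — white Gaussian noise spectrally shaped to a
  power-law PSD with exponent 1 (default), normalized to unit variance,
  independent per channel and trial. This is the simplest stationary
  background consistent with M/EEG spectra; it deliberately omits
  ocular/cardiac/muscle artifacts, line noise, and non-stationary
  aperiodic drift.
* **Sustained oscillations** with random phase per trial and channel: an
  alpha rhythm (10 Hz, amplitude 1.0) and a beta rhythm (20 Hz,
  amplitude 1.0) in units of the background sd. Event-related responses
  are *multiplicative amplitude modulations* of these ongoing rhythms —
  matching the definition of ERD/ERS as magnitude changes of ongoing
  activity, not additive bursts:
  - alpha-ERD: amplitude dip of depth 0.5 over [0.32, 0.76] s,
  - beta-ERD: dip of depth 0.6 over [0.16, 0.55] s,
  - beta-ERS ("beta rebound"): surge of gain 0.8 over [0.61, 3.68] s.
  The windows are the canonical latencies of pain-induced ERSPs; the
  amplitudes and depths were fixed once so that all three responses are
  detectable at the 0.5-z grand-average threshold with magnitudes of
  roughly 1–3 z, the scale typical of trial-averaged pain ERSP maps.
* **Modulation envelopes** use raised-cosine ramps of 100 ms to avoid
  spectral splatter. ERD ramps sit *outside* their window, so the mean
  envelope inside the window equals the nominal modulated level exactly;
  ERS ramps sit *inside* its window, so the condition-modulated surge has
  support exactly [0.61, 3.68] s and cannot leak into the adjacent
  beta-ERD measurement range (with outside ramps the surge began at
  0.51 s and induced spurious condition effects on beta-ERD at n = 34).
* **Condition and group effects** multiply the beta-ERS gain only
  (defaults: during 0.6, after 0.8 relative to before; CP 0.9 relative
  to HC — a non-significant trend at n = 17/group, as in the findings
  this generator emulates). Per-subject effect dispersion is a
  truncated-normal multiplicative factor (sd 0.2). With all modulators
  at 1 the generative law is identical across cells — an exchangeable
  null used for type-I-error calibration.
* **Stimulus artifact** — a deterministic bump of amplitude 15 over
  [0, 70] ms on all channels, standing in for the electrical stimulation
  transient; and an optional phase-locked evoked transient (Gaussian,
  amplitude 1, latency 120 ms, width 20 ms) on response channels.

Modulation is applied only on 4 of 12 "response" channels so spatial
maps have structure; the background rhythms are present everywhere.
Recording-site labels (MNI/Donders, ~11:6 per group) select the
power-line frequencies used by the notch filter.

What passing tests on this generator do **not** show about real data:
there is no volume conduction or sensor geometry, no physiological
artifacts, no non-stationarity across a block, and effect sizes are
cleaner than in vivo. The tests demonstrate that the *analysis chain*
recovers what was injected and that the inference layer is calibrated —
not that real recordings would yield these effect sizes.

## Preprocessing

The stimulus artifact span [0, 70] ms is replaced by linear
interpolation between the last clean sample before and the first clean
sample after the span (the span endpoints are treated as contaminated —
the artifact covers its own onset sample). Filtering is zero-phase
(forward–backward) so ERSP latencies are not shifted: a 4th-order
Butterworth bandpass (1–200 Hz, upper edge capped at 0.9 Nyquist) and
second-order IIR notches at the site's line frequencies. The notch
quality factor defaults to 60 per pass: under two-pass application the
magnitude response is squared, and Q = 60 keeps bands ±2 Hz from the
line frequency within 10% while attenuating the line itself by ≥ 95%.
Bad channels are excluded when the robust z-score of their RMS exceeds
5; the robust scale (1.4826·MAD) is floored at 10% of the median RMS
because with ~12 channels, many statistically identical, the MAD can
collapse and flag benign channel-to-channel differences. An explicit
exclusion list overrides the automatic criterion.

## Time–frequency decomposition

Morlet wavelets are parameterized by the mother wavelet's central
frequency (1 Hz) and temporal FWHM (3 s); at analysis frequency f the
Gaussian sd is σ_t(f) = FWHM/(2√(2 ln 2)) · 1/f ≈ 1.274/f s, i.e., the
spectral sd is σ_f = f/8 Hz. Wavelets are amplitude-normalized so a
unit sinusoid yields plateau magnitude 1. Spectrograms are magnitude
(not power), on a default 1-Hz grid over [1, 60] Hz.

Convolution is computed in the frequency domain: the epoch is
reflection-padded by half the longest wavelet support, transformed
once, multiplied by each wavelet's spectrum (an analytic Gaussian
centred on f, truncated at ±5σ_f where the gain is < 1e−5), and the
narrow product band is inverted with a small FFT common to all
frequencies. This returns the exact band-limited complex envelope on a
uniform, optionally decimated grid (tests pin it against direct
time-domain convolution to ~1e−6). Values within one σ_t(f) of an
epoch edge can be flagged as edge-contaminated; validation uses the
epoch interior.

Each trial's magnitude map is z-scored per (channel, frequency) against
its own pre-stimulus baseline [−1.5, −0.5] s (mean and sd over baseline
bins, sd with ddof = 1; a constant trace raises an error naming the
channel and frequency). Per-trial z-scoring before trial averaging is
the primary order; an average-then-z mode is exposed for sensitivity
analysis. Phase-locked evoked averages are trial means corrected to
their own [−2, 0] s baseline.

## ERSP windows and measures

Windows are detected once, on the grand-average z-map over the analysis
ROI (all trials, conditions and participants), and then held fixed:
the band-mean trace (alpha [8, 13] Hz on the "sensor" ROI; beta
[15, 30] Hz on the "brain" ROI) is thresholded at |z| ≥ 0.5, and each
maximal sign-constant run becomes a window. Positive and negative
excursions are detected separately, so a fast ERD→ERS transition cannot
fuse into one window when no time bin samples the brief sub-threshold
crossing. A run is discarded only if its *peak* lies before stimulus
onset; a kept run's start is clipped to 0, since wavelet smoothing
(σ_t ≈ 50–80 ms in the beta band) spreads genuinely post-stimulus
responses a few tens of milliseconds backward in time. When several
runs share a sign, the one containing the canonical latency (early for
ERD, late for the rebound) is used, falling back to the longest.

Per participant × condition, the **magnitude** is the mean z over the
fixed band × window (× ROI channels); the **duration** is the length of
the longest contiguous run with sign·trace ≥ 2 z after smoothing the
band-mean trace with a centred 500-ms moving average that shrinks at
the trace edges (window length rounded to an odd number of bins). Only
runs starting at or after t = 0 count; disjoint runs are not summed.
A rectangular 1-s pulse of 3 z therefore yields 5/6 s — the smoothing
erodes 1/12 s per side — which the tests pin against a direct
moving-average oracle. Location maps evaluate the magnitude per channel
as a desk-scale stand-in for cortical vertex maps.

## Baseline spectra

Welch periodograms of each trial's [−2, 0] s baseline (1-s Hann
segments, 50% overlap — 1 Hz resolution), averaged over trials and ROI
channels, restricted to [1, 60] Hz and divided by the total power over
that range (the normalization range is fixed to the analysis range).
Band peaks are the within-band maxima of relative power; an optional
flag detrends a log-log linear 1/f fit (excluding the alpha/beta bands)
before peak picking. Group and condition comparisons run per-frequency
permutation t-tests with Benjamini–Hochberg correction. Note that unit
normalization couples bins: adding band-limited power to one condition
necessarily depresses the relative power of all other bins slightly.

## Inference layer

**ANOVA-type statistic (ATS).** The rank-based test for one
between-subject factor (group) crossed with one within-subject factor
(condition), complete profiles: all N·t observations are mid-ranked
together; cell relative effects are p̂_ij = (mean rank − ½)/(N·t); the
statistic for a contrast C with projection T = C′(CC′)⁻C is
F = N·p̂′Tp̂ / tr(TV̂) with V̂ the block-diagonal (over groups)
covariance estimate, referred to an F distribution with Box-approximated
numerator df f̂ = tr(TV̂)²/tr((TV̂)²) and denominator ∞ — the
convention of the standard ATS output table, whose bracketed df is the
numerator df. For the between-subject effect a finite Box-approximated
denominator df and its p-value are reported additionally. Constant data
(all ranks tied) is flagged degenerate with statistic 0, p = 1, and
relative effects ½. Correctness is pinned two ways: a golden fixture
computed by an independently written base-R implementation of the same
published construction (agreement to 1e−8), and a 1000-replicate null
simulation at n = 17/group showing rejection rates within [0.03, 0.07]
for all three effects.

**Post hoc contrasts** are Wilcoxon signed-rank tests on the
before-vs-during and before-vs-after pairs, Holm-adjusted (the
least-assumption FWER method; configurable). Identical paired samples
give p = 1; fewer than 5 informative pairs sets a small-sample flag.

**Cluster-based permutation tests** threshold the elementwise t-map at
the two-sided p < 0.05 critical value, form 4-connected clusters in the
(frequency, time) lattice separately for positive and negative
excursions, and compare each cluster's summed t (mass) to the
permutation null of the maximum absolute mass — subject sign-flips for
paired designs, label shuffles for independent groups. P-values use the
add-one estimator (1+b)/(1+m), bounded below by 1/(n_perm+1).

**Permutation t-maps** apply the same permutation schemes per location
(channel or frequency bin), with each location's p from its own |t|
null and Benjamini–Hochberg adjustment across locations.

**Rank utilities.** Spearman's ρ uses mid-ranks and the t
approximation (constant input raises — ρ is undefined). The rank-sum
test reports the tie-corrected normal approximation and the effect size
r = |Z|/√N.

All permutation procedures take an explicit seed and are exactly
reproducible.

## Ratings and the pipeline

Subjective 0–10 ratings are condition-level means (defaults 3.8 / 3.45
/ 3.3 for before/during/after, matching the behavioral pattern of a
sequential CPM protocol) plus a subject offset (sd 1.2) and noise
(sd 0.5), clipped to [0, 10]. A coupling parameter ties ratings to the
subject's realized beta-ERS gain; the default of 0 reproduces the null
neural–behavioral correlation case, and the correlation analysis
(Spearman on before-minus-during changes) is exercisable at any
coupling.

`run_full` executes simulate → preprocess → TFR → window detection →
measures → ratings → statistics and emits a report (JSON + CSV) whose
every number is a pure function of (inputs, config, seed); provenance
records the config hash, seed and stage timings. Stage failures abort
with the stage name. Heavy optional products (cluster tests, PSD
comparisons, location maps) can be disabled individually.

## Problem sizes used in validation

The test suite runs the full study layout (2 × 17 participants × 3
conditions × 22 trials) where the claim depends on it, and scales other
knobs to desk size as the package's own choice of validation budget:
end-to-end pattern runs and replicate-recovery runs use a 300 Hz
sampling rate (all analysis frequencies ≤ 30 Hz), a band-restricted
frequency grid (8–13 and 15–30 Hz), 4× time decimation of spectrograms,
and 5-channel montages where non-ROI channels do not enter the measured
quantity. Cluster-test calibration uses 500 null replicates of a
30 × 40 bin grid with 500 permutations each; the modulator-recovery
check uses 50 replicate datasets. The acceptance script
(`scripts/acceptance.py`) runs the same pipeline at the study layout
with 1000 permutations.

## Known limitations

* The ATS implementation covers the complete two-factor longitudinal
  design only (no missing cells); the denominator-df convention for the
  between-subject effect is reported in the output rather than assumed
  unique.
* Window detection near stimulus onset inherits the wavelet's temporal
  blur; detected ERD onsets are reported from t = 0 when the response
  leaks backward, so sub-50-ms onset latencies are not meaningful.
* The magnitude measure mixes band bins with and without oscillatory
  signal; it is proportional to the injected modulation (ratios are
  recovered within a few percent) but its absolute z value depends on
  the band/grid choice.
* The simulator's 1/f background is stationary; baseline-spectrum
  comparisons are calibrated under that assumption.
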