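# cpmosc

Oscillatory-marker analysis of conditioned pain modulation (CPM)
experiments: from epoched multi-channel electrophysiological trials to
time–frequency z-maps, event-related spectral perturbation (ERSP)
statistics, baseline power spectra, and a nonparametric group × condition
inference layer — together with a synthetic-trial generator carrying
known injected effects, so every stage of the chain can be validated
against ground truth.

## Who this is for

CPM is a "pain inhibits pain" paradigm: a conditioning stimulus at one
body site attenuates the perceived intensity — and the cortical
oscillatory response — of a painful test stimulus elsewhere. Analyses of
such experiments quantify stimulus-locked changes of ongoing rhythms:
alpha-band (8–13 Hz) desynchronization (alpha-ERD), beta-band
(15–30 Hz) desynchronization (beta-ERD), and the post-stimulus beta
rebound (beta-ERS) over sensorimotor cortex, compared across
experimental blocks (before / during / after conditioning) and between a
chronic-pain and a control group. `cpmosc` packages that entire analysis
as tested, reusable library code for researchers who want to run it on
simulated data, benchmark its statistical behaviour, or adapt it to
their own epoched recordings.

## What it computes

* **Simulation** — 1/f background plus sustained alpha/beta rhythms
  whose amplitudes are multiplicatively modulated after the stimulus
  (ERD dips, ERS surge with condition/group modulators), a stimulus
  artifact, and optional evoked transients; exchangeable-null
  configurations for calibration. HDF5 container I/O.
* **Preprocessing** — artifact interpolation over [0, 70] ms, zero-phase
  Butterworth bandpass (1–200 Hz) and power-line notches per recording
  site, automatic bad-channel exclusion.
* **Time–frequency** — Morlet spectrograms (mother wavelet: central
  frequency 1 Hz, temporal FWHM 3 s; σ_t(f) = 1.274/f s) on [1, 60] Hz,
  z-scored per trial against the [−1.5, −0.5] s baseline.
* **ERSP measures** — windows detected on the grand-average z-map at
  |z| ≥ 0.5 and held fixed; per-participant magnitude (mean z over the
  fixed band × window) and duration (longest post-stimulus run ≥ 2 z of
  the 500-ms-smoothed band trace); per-channel location maps.
* **Baseline spectra** — Welch relative power (1-s Hann segments, 50%
  overlap) of the [−2, 0] s baseline, band peaks and band power.
* **Statistics** — rank-based 2 × 3 ANOVA-type tests (ATS) with
  relative treatment effects and Box-approximated degrees of freedom;
  Holm-adjusted Wilcoxon post hoc contrasts; cluster-based permutation
  tests on time–frequency maps; permutation t-maps with
  Benjamini–Hochberg FDR; Spearman and rank-sum utilities. For the
  hypothesis contrast C, the ATS is F = N·p̂′Tp̂/tr(TV̂) with
  T = C′(CC′)⁻C, p̂ the vector of cell relative effects from pooled
  mid-ranks, and numerator df tr(TV̂)²/tr((TV̂)²).

See `docs/methods.md` for the model, parameter defaults and the design
decisions behind each stage.

## Worked example

```python
import numpy as np
from cpmosc import AnalysisConfig, SimulationConfig, run_full

config = AnalysisConfig(
    simulation=SimulationConfig(n_per_group=8, trials_per_block=12,
                                sampling_rate=300.0),
    tfr_freqs=np.r_[np.arange(8.0, 14.0), np.arange(15.0, 31.0)],
    n_perm=500,
    seed=1,
)
report = run_full(config)

w = report.windows["beta_ers"]
print(f"beta-ERS window: [{w['t_start']:.2f}, {w['t_end']:.2f}] s")
ats = report.ats["beta_ers_magnitude"]
print(f"condition effect on beta-ERS magnitude: "
      f"ATS[{ats['condition']['df']:.2f}] = {ats['condition']['statistic']:.2f}, "
      f"P = {ats['condition']['p']:.2g}")
print(f"group effect: ATS[{ats['group']['df']:.2f}] = "
      f"{ats['group']['statistic']:.2f}, P = {ats['group']['p']:.3f}")
ph = report.posthoc["beta_ers_magnitude"]
print("post hoc (Holm):", {p: round(float(q), 4)
                           for p, q in zip(ph["pairs"], ph["p_adjusted"])})
print(f"cluster test before vs during: min corrected p = "
      f"{report.clusters['before_vs_during']['min_p']:.4f}")
print(report.summary[report.summary.measure == "beta_ers_magnitude"]
      .round(2).to_string(index=False))
```

prints

```
beta-ERS window: [0.64, 3.66] s
condition effect on beta-ERS magnitude: ATS[1.87] = 417.00, P = 1.2e-170
group effect: ATS[1.00] = 0.37, P = 0.544
post hoc (Holm): {'before-during': 0.0001, 'before-after': 0.0001}
cluster test before vs during: min corrected p = 0.0020
           measure group condition  mean  sem  std
beta_ers_magnitude    CP    before  2.04 0.06 0.17
beta_ers_magnitude    CP    during  1.20 0.05 0.14
beta_ers_magnitude    CP     after  1.65 0.04 0.13
beta_ers_magnitude    HC    before  2.09 0.10 0.29
beta_ers_magnitude    HC    during  1.31 0.05 0.14
beta_ers_magnitude    HC     after  1.67 0.07 0.21
```

Reading the output: the beta rebound is detected close to its injected
window ([0.61, 3.68] s); its magnitude drops during conditioning
(group means 2.0 → 1.2 z) and partially recovers afterwards; the ATS
finds a strong condition effect, no group effect, and both post hoc
contrasts survive Holm adjustment; the cluster test localizes the
reduction in the time–frequency plane. The bracketed ATS value is the
Box-approximated numerator df.

The same stages are available from the shell via `cpmosc`
(`simulate`, `preprocess`, `tfr`, `ersp`, `psd`, `stats`, `run-all`),
each a thin wrapper over the library, e.g.

```sh
cpmosc simulate --seed 1 --out ds.h5
cpmosc preprocess --in ds.h5 --out pre.h5
cpmosc run-all --seed 1 --out-dir results/
```

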