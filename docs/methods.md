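# Methods

This note documents the signal model, the estimators, the numerical
choices and the known limitations of the implementation.

## Synthetic signal model

A session consists of one run per stimulus paradigm. Each run holds
`trials_per_frequency x 5` trials of 15 s at 256 Hz across 8 occipital
channels (PO7, PO3, POz, PO4, PO8, O1, Oz, O2), in a seeded random target
order. Trial phases and their marker codes: fixation (2 s), target
presentation (2 s, marker payload = target index), preparation (1 s),
stimulation (5 s), rest (5 s).

### Evoked component

During the stimulation phase of a trial attending frequency `f`, channel
`e` receives

```
sum_h  A[e, h] * g_paradigm * c * sin(2 pi h f t + phi[e, h]),   h = 1..Nh
```

with `Nh = 4` harmonics (rows above Nyquist are truncated and logged).
Default amplitudes follow a `1/h` harmonic decay scaled by a channel
topography (Oz 1.2; O1/O2 1.0; POz 0.8; remaining parieto-occipital
channels 0.6), reflecting the occipital dominance of the response. The
paradigm gain `g` encodes that On-Off stimuli evoke roughly three times
the checkerboard response amplitude: `g = 1` for OOR/OOS and `g = 1/3`
for CBR/CBS.

### Background

Per channel: white Gaussian noise spectrally shaped by `|f|^(-gamma/2)`
(`gamma = 1`, DC removed), plus an 8-13-Hz band-pass-filtered alpha
component at half the pink-noise amplitude, the sum normalized to an RMS
of 10 uV. RNG substreams are spawned per paradigm and per trial from the
master seed (`numpy.random.SeedSequence`), so runs are byte-reproducible
and trials are statistically independent. The noise streams are drawn
even when the background is disabled, keeping trial ordering independent
of the noise settings.

### SNR calibration

`target_snr_db` (default -11 dB, defined at paradigm gain 1, i.e. for
On-Off runs) controls the factor `c`. The calibration deliberately
targets the *downstream estimator* rather than an analytic power ratio:
the wide-band SNR estimator sums nearest-bin values of a Hann-tapered,
segment-averaged periodogram, and the taper spreads each sinusoid's power
across neighbouring bins, so only about two thirds of an on-grid
harmonic's power lands in its own bin. The generator therefore measures
the harmonic-bin power `P_harm(e)` of the deterministic gain-1 evoked
component with exactly that estimator and solves

```
mean_e 10 log10( c^2 P_harm(e) / (rms^2 / df) ) = target_snr_db
```

where `rms^2/df` is the background's expected contribution to the
denominator bins. Two consequences, verified in the tests: the measured
SNR tracks the target within about 2 dB for targets <= 0 dB (slightly
above it, because the leaked harmonic power still sits in the epoch's
spectrum), and the *measured* wide-band SNR saturates near +3 dB no
matter the amplitude (once the evoked component dominates, leaked
harmonic power grows as fast as the harmonic bins themselves). The
amplitude scale itself is monotone and unbounded in the target.

With the defaults, On-Off runs measure near -9.5 dB and checkerboard runs
about 6.4 dB lower (the 1/3 gain), preserving the ordering reported for
real recordings of these paradigms.

## Spectral estimators

- **PSD**: average of one-sided periodograms over non-overlapping 2-s
  Hann-tapered segments (`scipy.signal.welch`, density scaling, constant
  detrend). Native resolution 0.5 Hz; results are reported on the
  2-50 Hz grid (97 bins) while the full grid is kept for the SNR.
- **Wide-band SNR**: `10 log10(P_harm / (P_total - P_harm))` per channel,
  harmonics located by nearest-bin lookup on the full one-sided grid,
  then averaged across channels in dB. A cap of 300 dB guards the
  zero-residual case.
- **Contrast maps**: per (channel, frequency) two-sample Wilcoxon
  rank-sum tests of stimulation vs. no-stimulation per-epoch PSD values,
  Bonferroni-corrected at alpha = 0.01 over all 8 x 97 cells (a
  signed-rank paired variant is available). The family-wise error
  control is verified on null data in the acceptance suite.

## Detectors

All three share one contract: score every candidate frequency on a
window `X` (channels x samples) and return the argmax, ties broken
toward the lowest frequency (logged).

- **CCA**: the largest canonical correlation between `X` and the sin/cos
  harmonic template `Y_f` (rows `sin/cos(2 pi k f t)`, `k = 1..Nh`),
  solved as a generalized symmetric eigenproblem on covariance matrices
  with a relative ridge of `1e-9 * trace/dim` for conditioning. Tests
  pin it to an independent QR/SVD oracle within 1e-8.
- **FBCCA**: `X` is filtered into five sub-bands (Chebyshev-I order 4,
  0.5-dB ripple, 6/9/13/18/22-90 Hz, applied zero-phase), CCA is run per
  sub-band, and scores combine as `sum_n w(n) rho_n^2` with
  `w(n) = n^-1.25 + 0.25`. With one all-pass band and unit weight this
  reduces exactly to the squared CCA correlation. Note that zero-phase
  application doubles the passband ripple, so a passband tone can lose
  up to ~1 dB (about 11% in amplitude) if it sits at a ripple trough.
- **MEC**: least squares fits `X ~ G Y_f`; the residual's covariance is
  eigendecomposed and the smallest-eigenvalue eigenvectors are kept until
  they first carry 10% of the residual energy, scaled `v_i / sqrt(l_i)`
  so each filtered residual has unit energy (eigenvalue floor
  `1e-12 * max`). The candidate score averages squared projections of the
  filtered signal onto the template rows over filters and harmonics; on
  pure noise this normalization makes the expected score dimensionless
  and close to 1. A strict-literal mode summing unsquared projections is
  kept behind a flag for comparison only, since it cancels for arbitrary
  phases.

## Pseudo-online assessment

Detection epochs span 6 s (1 s pre-onset + 5 s stimulation). Windows of
1 s advance by 0.05 s (101 windows); every window is scored, but only
windows ending after stimulation onset feed the decision counter.

**Decision rule.** The default rule, `target_confirmation`, marks a trial
detected when three consecutive windows pick the trial's attended
frequency; DT is the end time of the confirming window, and undetected
trials count as incorrect with DT equal to the stimulation length. This
is the reading under which "number of correct detections" defines the
accuracy and high-SNR epochs produce mean DTs around one second. The
alternative `first_agreement` rule (first triple of *any* agreeing
candidate decides) is provided for comparison, but it is degenerate at
this window geometry: consecutive windows share 95% of their samples and
hence almost always agree, so the rule latches onto the first few
post-onset windows -- whose samples are still almost entirely pre-onset
background -- and pins accuracy near chance at every SNR while reporting
DT = 0.15 s. The constant-detector mechanics (DT = 0.15 s when the
answer matches the target) are identical under both rules.

**Metrics.** DA is the fraction of correctly detected trials. ITR in
bits/min is `(60/DT) [log2 N + DA log2 DA + (1-DA) log2((1-DA)/(N-1))]`,
clamped to 0 at or below the 1/N chance level and using the
`0 log 0 = 0` limit at DA = 1. Cross-condition comparisons use a
Kruskal-Wallis omnibus test with pairwise Mann-Whitney follow-ups under
Holm correction, reported at the 0.001/0.01/0.05 tiers.

## Generator realism and limitations

The generator reproduces the statistical structure the analysis relies
on -- harmonic responses over a 1/f + alpha background with an occipital
topography, realistic trial timing and marker bookkeeping, and the
On-Off/checkerboard gain ratio -- but it is deliberately simple:

- Phases are fixed (default zero) and the evoked response is strictly
  stationary within the stimulation window; real SSVEPs show onset
  transients, latency jitter and amplitude drift.
- The background is Gaussian and channel-independent; real EEG has
  strong inter-channel correlation, non-Gaussian artifacts (blinks,
  muscle) and nonstationary alpha. Absent spatial noise correlation,
  spatial-filtering methods (MEC) gain less than they do on real data.
- The paradigm effect is a single gain factor; real checkerboard
  responses also differ spectrally (pattern-reversal responses appear at
  twice the alternation rate).
- Measured wide-band SNR saturates near +3 dB (see calibration above),
  so "high SNR" conditions should be set via targets <= 0 dB or by
  disabling calibration (`target_snr_db=None`) and scaling amplitudes.
- Per-frequency metric differences (e.g. the alpha-band bias against
  8.57/10.91 Hz) emerge qualitatively but are not calibrated to any
  particular dataset; headline numbers from real 27-subject recordings
  are not reproducible from synthetic data.

## Numerical choices

- All filtering is zero-phase (`sosfiltfilt`/`filtfilt`), so epochs keep
  their time alignment; filter stability is checked at design time.
- Covariance eigenproblems use symmetric solvers (`scipy.linalg.eigh`)
  with ridge/floor regularization rather than explicit inversion.
- File round-trips store samples as `%.17g` text, which is lossless for
  IEEE doubles.
- Problem sizes in tests and the acceptance script (trials per
  condition, simulation counts) are chosen to keep the whole suite under
  a few minutes on one CPU while leaving binomial confidence margins
  around every stochastic assertion; tolerances come from analytic
  closed forms, independent oracles, or 95% confidence intervals, never
  from tuning toward observed outputs.
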