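# ssvep-assess

Training-free detection of steady-state visually evoked potentials (SSVEP)
and pseudo-online assessment of detection accuracy, detection time and
information transfer rate, with a synthetic EEG session generator for
desk-scale experiments.

## Background

An SSVEP brain-computer interface presents several targets flickering at
distinct frequencies; attending one of them drives an oscillatory occipital
response at that frequency and its harmonics. The interface recovers the
attended target directly from the EEG, without per-user training, by
comparing the signal against harmonic reference templates.

This package implements the complete assessment workflow:

- **Synthetic sessions** (`ssvep_assess.synthetic_data`): multi-channel
  occipital EEG (8 channels, 256 Hz) with harmonic evoked responses embedded
  in 1/f pink noise plus an alpha-band component, organised into
  15-s trials (fixation 2 s, target presentation 2 s, preparation 1 s,
  stimulation 5 s, rest 5 s), 8 trials per frequency per run. The five
  default stimulation frequencies {8.5714, 10.9091, 15, 20, 24} Hz are the
  ones realizable on a 240-Hz display (refresh divided by 28, 22, 16, 12,
  10 frames). Four stimulus paradigms are modelled through a response-gain
  factor: On-Off rectangular/sinusoidal (OOR/OOS, gain 1) and checkerboard
  rectangular/sinusoidal (CBR/CBS, gain 1/3).
- **Recording I/O** (`ssvep_assess.recording_io`): a lossless delimited-text
  + JSON-sidecar container, a read-only EDF adapter, zero-phase
  band-pass/notch preprocessing, and marker-driven extraction of
  stimulation (5 s), no-stimulation (pre-onset) and detection (6 s,
  starting 1 s before onset) epochs.
- **Spectral analysis** (`ssvep_assess.spectral`): segment-averaged
  Hann-tapered PSD (2-s segments, 0.5-Hz resolution), wide-band SNR
  (harmonic power over all remaining broadband power, in dB) and
  Bonferroni-corrected stimulation-vs-rest contrast maps.
- **Detectors** (`ssvep_assess.detectors`): canonical correlation analysis
  (CCA), filter-bank CCA (FBCCA, five Chebyshev-I sub-bands with weighted
  squared correlations) and minimum energy combination (MEC).
- **Assessment** (`ssvep_assess.evaluation`): 1-s windows slid by 0.05 s
  over each detection epoch; a trial is detected when three consecutive
  windows confirm the attended frequency, the detection time (DT) is the
  end of the confirming window, and accuracy (DA), DT and the information
  transfer rate (ITR, bits/min) are tabulated per method, paradigm and
  frequency, with Kruskal-Wallis / pairwise rank statistics across
  conditions.

## Worked example

```python
import numpy as np
from ssvep_assess import (SyntheticConfig, generate_session, run_assessment,
                          extract_epochs, compute_psd, wideband_snr)

config = SyntheticConfig(seed=7)                    # -11 dB On-Off target SNR
recordings = generate_session(config, trials_per_frequency=2,
                              paradigms=("OOR", "CBR"))

for paradigm, rec in recordings.items():
    epochs = extract_epochs(rec, "stimulation")
    snr = np.mean([wideband_snr(compute_psd(e), e.target_frequency)
                   for e in epochs])
    print(f"{paradigm}: {len(epochs)} trials, mean wide-band SNR "
          f"{snr:+.2f} dB")

table = run_assessment(recordings, methods=("cca", "fbcca"))
summary = (table.groupby(["method", "paradigm"])
                .agg(DA=("DA", "mean"), DT=("DT_mean", "mean"))
                .round(3))
print(summary)
```

Output:

```text
OOR: 10 trials, mean wide-band SNR -9.41 dB
CBR: 10 trials, mean wide-band SNR -16.19 dB
                  DA     DT
method paradigm
cca    CBR       0.5  3.070
       OOR       1.0  0.610
fbcca  CBR       1.0  1.565
       OOR       1.0  0.550
```

The qualitative pattern matches what the real-EEG literature reports:
On-Off stimuli yield distinctly higher wide-band SNR than checkerboard
stimuli (~6.5 dB here, from the 1/3 response gain), detection is harder
and slower on checkerboard runs, and the filter bank recovers part of
the gap by exploiting harmonic structure.

## Command line

The `ssvep-assess` entry point chains the same stages:

```sh
ssvep-assess simulate  --seed 1 --out results/run       # one run per paradigm
ssvep-assess preprocess --in results/run/run_OOR.tsv --out results/pre.tsv
ssvep-assess epochs    --in results/pre.tsv --kind detection --out results/epochs.h5
ssvep-assess evaluate  --epochs results/epochs.h5 --method all --out results/eval
ssvep-assess compare   --metrics results/eval/metrics.csv --out results/cmp.json
ssvep-assess full-run  --seed 1 --out results/full      # everything at once
```

All stages accept `--config <file>` (JSON or YAML, unknown keys rejected
with a suggestion); every output directory records the seed and a hash of
the effective configuration.

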