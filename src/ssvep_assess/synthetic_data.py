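"""Synthetic SSVEP session generator.

Generates multi-channel EEG runs with the statistical structure the
downstream analysis assumes: harmonic steady-state responses at the
stimulation frequency, embedded in 1/f^gamma (pink) background noise with an
additive alpha-band component, organised into the run/trial/phase layout of
a five-target SSVEP selection task (40 trials per run, 15-s trials split
into fixation 2 s, target presentation 2 s, preparation 1 s, stimulation
5 s, rest 5 s).

The evoked component of channel *e* during stimulation at frequency *f* is

    sum_h  A[e, h] * g_paradigm * sin(2*pi*h*f*t + phi[e, h]),   h = 1..Nh

with harmonics above Nyquist silently truncated (logged).  Amplitudes
default to a 1/h decay weighted toward the occipital channels, and the
paradigm gain encodes that On-Off stimuli evoke roughly three times the
response amplitude of checkerboard stimuli.  A wide-band SNR target (in dB,
defined at paradigm gain 1) calibrates the evoked amplitude against the
background power analytically, so the generated stimulation segments attain
a controllable, measurable SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from ssvep_assess.recording_io import (
    DEFAULT_CHANNELS,
    PARADIGMS,
    Marker,
    MarkerCode,
    Recording,
)

logger = logging.getLogger(__name__)

#: The five stimulation frequencies as printed on the stimulus interface,
#: derived from a 240-Hz screen refresh divided by 28, 22, 16, 12 and 10.
DEFAULT_FREQUENCIES = (8.5714, 10.9091, 15.0, 20.0, 24.0)


def stimulation_frequencies(refresh_rate_hz: float = 240.0,
                            frame_divisors: Sequence[int] = (28, 22, 16, 12, 10)
                            ) -> tuple[float, ...]:
    """Stimulation frequencies realizable on a fixed-refresh display.

    Each flicker frequency is the refresh rate divided by an integer frame
    count, e.g. 240 Hz / 28 frames = 8.5714 Hz.
    """
    return tuple(refresh_rate_hz / d for d in frame_divisors)


# occipital channels (O1, Oz, O2) respond strongest; Oz most of all
_DEFAULT_CHANNEL_WEIGHTS = {
    "PO7": 0.6, "PO3": 0.6, "POz": 0.8, "PO4": 0.6, "PO8": 0.6,
    "O1": 1.0, "Oz": 1.2, "O2": 1.0,
}

_DEFAULT_PARADIGM_GAIN = {"OOR": 1.0, "OOS": 1.0, "CBR": 1.0 / 3.0, "CBS": 1.0 / 3.0}


@dataclass(frozen=True)
class StimulusSpec:
    """The set of flickering targets of one run."""

    paradigm: str = "OOR"
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    n_targets: int = 5

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"paradigm must be one of {PARADIGMS}")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("stimulation frequencies must be positive")
        if len(set(self.frequencies)) != len(self.frequencies):
            raise ValueError("stimulation frequencies must be pairwise distinct")
        if self.n_targets != len(self.frequencies):
            raise ValueError("n_targets must equal the number of frequencies")


@dataclass(frozen=True)
class TrialTiming:
    """Durations of the five trial phases, in seconds."""

    fixation_s: float = 2.0
    target_s: float = 2.0
    preparation_s: float = 1.0
    stimulation_s: float = 5.0
    rest_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("fixation_s", "target_s", "preparation_s",
                     "stimulation_s", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_s(self) -> float:
        return (self.fixation_s + self.target_s + self.preparation_s
                + self.stimulation_s + self.rest_s)

    @property
    def stimulation_onset_s(self) -> float:
        return self.fixation_s + self.target_s + self.preparation_s


def _default_amplitudes(channels: Sequence[str], n_harmonics: int) -> np.ndarray:
    weights = np.array([_DEFAULT_CHANNEL_WEIGHTS.get(c, 0.8) for c in channels])
    decay = 1.0 / np.arange(1, n_harmonics + 1)
    return np.outer(weights, decay)  # microvolts


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz.
    channels : tuple of str
        Ordered channel names.
    n_harmonics : int
        Harmonics in the evoked component (truncated below Nyquist).
    harmonic_amplitudes : ndarray (n_channels, n_harmonics), optional
        Per-channel, per-harmonic amplitudes in microvolts.  Default: 1/h
        decay, occipital channels strongest.
    harmonic_phases : ndarray (n_channels, n_harmonics), optional
        Phase offsets in radians (default zero).
    paradigm_gain : mapping paradigm -> float
        Multiplicative response amplitude; On-Off roughly 3x checkerboard.
    noise_gamma : float
        Spectral exponent of the 1/f^gamma background.
    alpha_amp : float
        Relative amplitude of the 8-13 Hz background component (0 disables).
    background_rms : float
        Per-channel background RMS in microvolts (0 disables noise).
    target_snr_db : float or None
        Wide-band SNR (harmonic power over remaining broadband power, dB,
        channel-averaged) that stimulation segments should attain at
        paradigm gain 1.  ``None`` uses the raw amplitudes unscaled.
    seed : int
        Master RNG seed; identical config + seed gives identical output.
    """

    fs: float = 256.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    n_harmonics: int = 4
    harmonic_amplitudes: np.ndarray | None = None
    harmonic_phases: np.ndarray | None = None
    paradigm_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PARADIGM_GAIN))
    noise_gamma: float = 1.0
    alpha_amp: float = 0.5
    background_rms: float = 10.0
    target_snr_db: float | None = -11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        ne = len(self.channels)
        if self.harmonic_amplitudes is None:
            self.harmonic_amplitudes = _default_amplitudes(self.channels,
                                                           self.n_harmonics)
        self.harmonic_amplitudes = np.atleast_2d(
            np.asarray(self.harmonic_amplitudes, dtype=float))
        if self.harmonic_amplitudes.shape != (ne, self.n_harmonics):
            raise ValueError("harmonic_amplitudes must have shape "
                             f"({ne}, {self.n_harmonics})")
        if np.any(self.harmonic_amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.harmonic_phases is None:
            self.harmonic_phases = np.zeros((ne, self.n_harmonics))
        self.harmonic_phases = np.atleast_2d(
            np.asarray(self.harmonic_phases, dtype=float))
        if self.harmonic_phases.shape != (ne, self.n_harmonics):
            raise ValueError("harmonic_phases must have shape "
                             f"({ne}, {self.n_harmonics})")
        if self.background_rms < 0:
            raise ValueError("background_rms must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


# ---------------------------------------------------------------------------
# component generators


def _rng_for(config: SyntheticConfig,
             rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def gen_background(config: SyntheticConfig, duration_s: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Background EEG: per-channel pink noise plus an alpha-band component.

    Pink noise is generated by spectrally shaping white Gaussian noise with
    ``|f|^(-gamma/2)`` (DC removed, hence zero mean); the alpha component is
    8-13 Hz band-pass-filtered white noise.  Each channel is normalized to
    ``background_rms`` microvolts RMS.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _rng_for(config, rng)
    n = int(round(duration_s * config.fs))
    ne = config.n_channels
    # draw deterministically even when noise is disabled, so the RNG stream
    # (and thus trial ordering downstream) does not depend on background_rms
    white = rng.standard_normal((ne, n))
    alpha_white = rng.standard_normal((ne, n))
    if config.background_rms == 0:
        return np.zeros((ne, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shaping = np.ones_like(freqs)
    if config.noise_gamma != 0:
        with np.errstate(divide="ignore"):
            shaping = np.where(freqs > 0, freqs, np.inf) ** (-config.noise_gamma / 2.0)
    shaping[0] = 0.0  # zero mean
    pink = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    out = pink
    if config.alpha_amp > 0:
        sos = signal.butter(4, [8.0, 13.0], btype="bandpass", fs=config.fs,
                            output="sos")
        alpha = signal.sosfiltfilt(sos, alpha_white, axis=1)
        alpha /= alpha.std(axis=1, keepdims=True)
        out = pink + config.alpha_amp * alpha
    out -= out.mean(axis=1, keepdims=True)
    out *= config.background_rms / out.std(axis=1, keepdims=True)
    return out


def _active_harmonics(config: SyntheticConfig, f: float) -> int:
    """Number of harmonics of f below Nyquist (truncation logged)."""
    nyq = config.fs / 2.0
    nh = min(config.n_harmonics, int(np.floor((nyq - 1e-12) / f)))
    if nh < config.n_harmonics:
        logger.info("truncating harmonics of %.4f Hz above Nyquist: "
                    "keeping %d of %d", f, nh, config.n_harmonics)
    return max(nh, 0)


def _evoked_matrix(config: SyntheticConfig, f: float, n_samples: int,
                   amplitude_scale: float) -> np.ndarray:
    t = np.arange(n_samples) / config.fs
    nh = _active_harmonics(config, f)
    out = np.zeros((config.n_channels, n_samples))
    for h in range(1, nh + 1):
        amp = (config.harmonic_amplitudes[:, h - 1] * amplitude_scale)[:, None]
        phase = config.harmonic_phases[:, h - 1][:, None]
        out += amp * np.sin(2.0 * np.pi * h * f * t[None, :] + phase)
    return out


def evoked_scale(config: SyntheticConfig, f: float,
                 duration_s: float = 5.0, seg_len_s: float = 2.0) -> float:
    """Amplitude scale that brings the wide-band SNR of a gain-1
    stimulation segment to ``target_snr_db``.

    The SNR estimator downstream averages Hanning-tapered periodograms and
    sums the nearest bins of the harmonics, so part of each harmonic's
    power leaks outside its bin.  The calibration therefore measures the
    harmonic-bin power of the deterministic gain-1 evoked component with
    the same estimator, and solves

        mean_e 10*log10( scale^2 * P_harm(e) / P_background(e) ) = target

    with ``P_background = background_rms^2 / df``, the background's
    contribution to the estimator's denominator.  (Because of taper
    leakage the *measured* SNR sits slightly below the target -- by about
    ``10*log10(1 + leaked/background)`` dB, under 2 dB at targets <= 0 --
    and saturates near +3 dB no matter the amplitude; the scale itself is
    monotone and unbounded in the target.)
    """
    if config.target_snr_db is None or config.background_rms == 0:
        return 1.0
    if _active_harmonics(config, f) < 1:
        return 1.0
    # calibrate on at least two full segments regardless of duration
    n_cal = int(round(max(duration_s, 2 * seg_len_s) * config.fs))
    sig = _evoked_matrix(config, f, n_cal, 1.0)
    if not np.any(sig):
        return 1.0
    nperseg = int(round(seg_len_s * config.fs))
    freqs, power = signal.welch(sig, fs=config.fs, window="hann",
                                nperseg=nperseg, noverlap=0,
                                detrend="constant", axis=1)
    df = freqs[1] - freqs[0]
    ks = np.arange(1, config.n_harmonics + 1)
    ks = ks[ks * f <= freqs[-1]]
    bins = np.unique([int(np.argmin(np.abs(freqs - k * f))) for k in ks])
    p_harm = power[:, bins].sum(axis=1)
    p_bg = config.background_rms ** 2 / df
    valid = p_harm > 0
    base_db = np.mean(10.0 * np.log10(p_harm[valid] / p_bg))
    return float(10.0 ** ((config.target_snr_db - base_db) / 20.0))


def gen_evoked(config: SyntheticConfig, f: float, duration_s: float,
               paradigm: str = "OOR", apply_snr_scale: bool = True) -> np.ndarray:
    """Deterministic harmonic SSVEP component at frequency ``f``.

    Channel *e* is ``sum_h A[e,h] * gain * sin(2 pi h f t + phi[e,h])`` over
    the harmonics below Nyquist.  ``apply_snr_scale`` additionally applies
    the wide-band-SNR calibration of :func:`evoked_scale`.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f >= config.fs / 2.0:
        raise ValueError(f"frequency {f} Hz is at or above Nyquist "
                         f"({config.fs / 2.0} Hz)")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    gain = config.paradigm_gain.get(paradigm, 1.0)
    scale = evoked_scale(config, f, duration_s) if apply_snr_scale else 1.0
    n = int(round(duration_s * config.fs))
    return _evoked_matrix(config, f, n, gain * scale)


# ---------------------------------------------------------------------------
# trial and session assembly


def generate_trial(config: SyntheticConfig,
                   stimulus: StimulusSpec,
                   timing: TrialTiming,
                   target_index: int,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, list[Marker]]:
    """One 15-s trial: background everywhere, evoked response added only
    during the stimulation phase, plus the five phase markers."""
    if not (0 <= target_index < stimulus.n_targets):
        raise ValueError(f"target_index {target_index} outside "
                         f"[0, {stimulus.n_targets})")
    rng = _rng_for(config, rng)
    fs = config.fs
    x = gen_background(config, timing.total_s, rng=rng)
    onset = int(round(timing.stimulation_onset_s * fs))
    n_stim = int(round(timing.stimulation_s * fs))
    f = stimulus.frequencies[target_index]
    x[:, onset:onset + n_stim] += gen_evoked(
        config, f, timing.stimulation_s, paradigm=stimulus.paradigm)
    t_target = timing.fixation_s
    t_prep = timing.fixation_s + timing.target_s
    t_rest = timing.stimulation_onset_s + timing.stimulation_s
    markers = [
        Marker(0, MarkerCode.FIXATION, None),
        Marker(int(round(t_target * fs)), MarkerCode.TARGET, target_index),
        Marker(int(round(t_prep * fs)), MarkerCode.PREPARATION, None),
        Marker(onset, MarkerCode.STIMULATION, None),
        Marker(int(round(t_rest * fs)), MarkerCode.REST, None),
    ]
    return x, markers


def generate_session(config: SyntheticConfig,
                     stimulus: StimulusSpec | None = None,
                     timing: TrialTiming | None = None,
                     trials_per_frequency: int = 8,
                     paradigms: Sequence[str] = PARADIGMS,
                     subject_id: str = "synthetic"
                     ) -> dict[str, Recording]:
    """Generate one Recording per paradigm.

    Each run contains ``trials_per_frequency`` trials per stimulation
    frequency in a seeded randomized order.  Per-run and per-trial RNG
    substreams are derived from the master seed, so the same config is
    byte-reproducible and individual trials are independent.
    """
    if trials_per_frequency < 1:
        raise ValueError("trials_per_frequency must be >= 1")
    stimulus = stimulus if stimulus is not None else StimulusSpec()
    timing = timing if timing is not None else TrialTiming()
    master = np.random.SeedSequence(config.seed)
    run_seeds = master.spawn(len(paradigms))
    recordings: dict[str, Recording] = {}
    n_trials = trials_per_frequency * stimulus.n_targets
    samples_per_trial = int(round(timing.total_s * config.fs))
    for paradigm, run_seed in zip(paradigms, run_seeds):
        run_stimulus = StimulusSpec(paradigm=paradigm,
                                    frequencies=stimulus.frequencies,
                                    n_targets=stimulus.n_targets)
        children = run_seed.spawn(n_trials + 1)
        order_rng = np.random.default_rng(children[0])
        targets = np.repeat(np.arange(stimulus.n_targets), trials_per_frequency)
        order_rng.shuffle(targets)
        data = np.empty((config.n_channels, n_trials * samples_per_trial))
        markers: list[Marker] = []
        for i, target in enumerate(targets):
            trial_rng = np.random.default_rng(children[i + 1])
            x, trial_markers = generate_trial(config, run_stimulus, timing,
                                              int(target), rng=trial_rng)
            offset = i * samples_per_trial
            data[:, offset:offset + samples_per_trial] = x
            markers.extend(Marker(m.sample + offset, m.code, m.payload)
                           for m in trial_markers)
        recordings[paradigm] = Recording(
            data=data, fs=config.fs, channel_names=config.channels,
            markers=markers, paradigm=paradigm, subject_id=subject_id,
            stim_frequencies=tuple(stimulus.frequencies))
    return recordings
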