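"""Power spectral density, wide-band SNR and condition-contrast maps.

The PSD of an epoch is the average of one-sided periodograms over
non-overlapping 2-s Hanning-tapered segments (density scaling, so that the
integral of the PSD approximates the signal variance).  At 256 Hz this gives
a native 0.5-Hz resolution; results are reported on the 2-50 Hz grid while
the full 0..fs/2 grid is kept for the wide-band SNR, which is defined as

    SNR = 10 log10( sum_k P(k f_i) / ( sum_f P(f) - sum_k P(k f_i) ) )

with the harmonic sum over k = 1..Nh using nearest-bin lookup and the
denominator over the whole one-sided grid.  Condition contrasts
(stimulation vs. no-stimulation) are per-(channel, frequency) two-sample
rank tests with Bonferroni correction over all channel-frequency cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from ssvep_assess.recording_io import Epoch

logger = logging.getLogger(__name__)

#: dB value returned when the non-harmonic residual power is zero.
SNR_CAP_DB = 300.0


@dataclass
class PSDResult:
    """Segment-averaged PSD of one epoch.

    ``freqs``/``power`` hold the 2-50 Hz reporting grid; ``full_freqs``/
    ``full_power`` the complete one-sided grid used by the wide-band SNR.
    Power units are microvolt^2 per Hz.
    """

    freqs: np.ndarray
    power: np.ndarray          # (n_channels, n_report_freqs)
    segment_count: int
    window: str
    full_freqs: np.ndarray
    full_power: np.ndarray     # (n_channels, n_full_freqs)
    channel_names: tuple[str, ...] = ()


@dataclass
class ContrastMap:
    """Channel-frequency significance map of a two-condition contrast."""

    pvalues: np.ndarray        # (n_channels, n_freqs)
    freqs: np.ndarray
    alpha: float
    corrected_alpha: float
    significant: np.ndarray    # boolean, pvalues < corrected_alpha
    channel_names: tuple[str, ...] = ()


def compute_psd(epoch: Epoch, seg_len_s: float = 2.0, overlap: float = 0.0,
                report_band: tuple[float, float] = (2.0, 50.0)) -> PSDResult:
    """Average one-sided periodogram over Hanning-tapered segments.

    Segments of ``seg_len_s`` seconds with fractional ``overlap`` are
    averaged per channel; a trailing remainder shorter than one segment is
    discarded.  The native frequency step is ``1/seg_len_s`` Hz, so no
    zero-padding is needed for the half-hertz reporting grid.
    """
    nperseg = int(round(seg_len_s * epoch.fs))
    if epoch.n_samples < nperseg:
        raise ValueError(f"epoch of {epoch.n_samples} samples is shorter than "
                         f"one {seg_len_s}-s segment ({nperseg} samples)")
    noverlap = int(round(overlap * nperseg))
    freqs, power = signal.welch(epoch.X, fs=epoch.fs, window="hann",
                                nperseg=nperseg, noverlap=noverlap,
                                detrend="constant", scaling="density", axis=1)
    step = nperseg - noverlap
    segment_count = (epoch.n_samples - nperseg) // step + 1
    lo, hi = report_band
    mask = (freqs >= lo) & (freqs <= hi)
    return PSDResult(freqs=freqs[mask], power=power[:, mask],
                     segment_count=segment_count, window="hann",
                     full_freqs=freqs, full_power=power,
                     channel_names=epoch.channel_names)


def _harmonic_bins(full_freqs: np.ndarray, f_i: float, n_harmonics: int
                   ) -> np.ndarray:
    """Nearest-bin indices of f_i and its harmonics; above-Nyquist harmonics
    are dropped with a log note."""
    nyq = full_freqs[-1]
    ks = np.arange(1, n_harmonics + 1)
    keep = ks * f_i <= nyq
    if not np.all(keep):
        logger.info("dropping %d harmonics of %.4f Hz beyond %.1f Hz",
                    int(np.sum(~keep)), f_i, nyq)
    bins = np.array([int(np.argmin(np.abs(full_freqs - k * f_i)))
                     for k in ks[keep]])
    return np.unique(bins)


def wideband_snr(psd: PSDResult, f_i: float, n_harmonics: int = 4,
                 average: bool = True) -> float | np.ndarray:
    """Wide-band SNR in dB: harmonic power over all remaining power.

    Computed per channel on the full one-sided grid, then (by default)
    averaged across channels in dB.  When all power sits in the harmonic
    bins the ratio diverges; the value is capped at ``SNR_CAP_DB``.
    """
    if f_i <= 0 or f_i > psd.full_freqs[-1]:
        raise ValueError(f"stimulation frequency {f_i} Hz outside the "
                         f"(0, {psd.full_freqs[-1]}] Hz grid")
    bins = _harmonic_bins(psd.full_freqs, f_i, n_harmonics)
    harmonic = psd.full_power[:, bins].sum(axis=1)
    total = psd.full_power.sum(axis=1)
    residual = total - harmonic
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_db = 10.0 * np.log10(harmonic / residual)
    snr_db = np.where(residual <= 0, SNR_CAP_DB, snr_db)
    snr_db = np.clip(snr_db, -SNR_CAP_DB, SNR_CAP_DB)
    return float(np.mean(snr_db)) if average else snr_db


def condition_contrast(stim: Sequence[Epoch], nostim: Sequence[Epoch],
                       alpha: float = 0.01, paired: bool = False,
                       seg_len_s: float = 2.0) -> ContrastMap:
    """Stimulation-vs-no-stimulation significance map.

    Per (channel, frequency) cell a two-sample Wilcoxon rank-sum test
    compares the per-epoch PSD values of the two conditions on the 2-50 Hz
    reporting grid; Bonferroni correction divides ``alpha`` by the number of
    cells.  ``paired=True`` switches to the signed-rank test on per-trial
    differences (requires equally many epochs per condition).
    """
    if len(stim) < 2 or len(nostim) < 2:
        raise ValueError("need at least two epochs per condition for a rank test")
    ch = stim[0].channel_names
    if any(e.channel_names != ch for e in list(stim) + list(nostim)):
        raise ValueError("all epochs must share the same channel set")

    def stack(epochs: Sequence[Epoch]) -> tuple[np.ndarray, np.ndarray]:
        psds = [compute_psd(e, seg_len_s=seg_len_s) for e in epochs]
        return psds[0].freqs, np.stack([p.power for p in psds])  # (n, Ne, Nf)

    freqs, a = stack(stim)
    _, b = stack(nostim)
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test requires equal epoch counts")
        res = stats.wilcoxon(a - b, axis=0)
    else:
        res = stats.ranksums(a, b, axis=0)
    pvalues = np.asarray(res.pvalue)
    n_cells = pvalues.size
    corrected = alpha / n_cells
    return ContrastMap(pvalues=pvalues, freqs=freqs, alpha=alpha,
                       corrected_alpha=corrected,
                       significant=pvalues < corrected,
                       channel_names=ch)
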