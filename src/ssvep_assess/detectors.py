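"""Training-free SSVEP frequency-recognition algorithms.

All three detectors share one contract: given a window ``X`` of shape
(n_channels, n_samples) and a set of candidate stimulation frequencies,
compute one score per candidate and pick the argmax (ties broken toward the
lowest frequency, logged).

CCA
    Max canonical correlation between ``X`` and a sin/cos harmonic
    reference template ``Y_f`` (rows ``sin(2 pi k f t), cos(2 pi k f t)``
    for k = 1..Nh), solved as a generalized symmetric eigenvalue problem on
    the covariance matrices with a small ridge for conditioning.

FBCCA
    CCA applied between the template and each of several band-pass-filtered
    sub-band versions of ``X`` (Chebyshev-I IIR filters, zero phase), the
    per-band correlations combined as ``sum_n w(n) rho_n^2`` with
    ``w(n) = n^-a + b`` (a = 1.25, b = 0.25).

MEC
    Minimum energy combination: least-squares fit of ``X`` onto the
    template rows leaves an SSVEP-free residual whose energy the spatial
    filters minimize; the columns of ``W`` are the smallest-eigenvalue
    eigenvectors of the residual covariance scaled to unit filtered-noise
    variance (``v_i / sqrt(lambda_i)``), keeping the smallest set carrying
    a fixed fraction (default 10%) of the residual energy.  The score of a
    candidate is the average squared projection of the spatially filtered
    signal onto the template rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, signal

from ssvep_assess.synthetic_data import StimulusSpec

logger = logging.getLogger(__name__)


class DegenerateSignalError(ValueError):
    """Raised when a window carries no usable signal (e.g. all zeros)."""


# ---------------------------------------------------------------------------
# reference templates


@dataclass
class ReferenceTemplate:
    """Sin/cos harmonic reference matrix for one candidate frequency.

    Rows alternate ``sin(2 pi k f t)`` and ``cos(2 pi k f t)`` for
    k = 1..Nh evaluated at ``t = n / fs`` with t = 0 at window start.
    """

    Y: np.ndarray      # (2 * n_harmonics_kept, n_samples)
    f: float
    n_harmonics: int   # harmonics actually kept (below Nyquist)
    fs: float


def build_reference(f: float, n_harmonics: int, fs: float,
                    n_samples: int) -> ReferenceTemplate:
    """Build the harmonic reference template ``Y_f``.

    Harmonic rows at or above Nyquist are dropped with a log note.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    nyq = fs / 2.0
    kept = min(n_harmonics, int(np.floor((nyq - 1e-12) / f)))
    if kept < 1:
        raise ValueError(f"fundamental {f} Hz is at or above Nyquist ({nyq} Hz)")
    if kept < n_harmonics:
        logger.info("template %.4f Hz: dropping %d harmonics above Nyquist",
                    f, n_harmonics - kept)
    if n_samples < 4 * kept:
        raise ValueError(f"window of {n_samples} samples too short for "
                         f"{kept} harmonics")
    t = np.arange(n_samples) / fs
    rows = []
    for k in range(1, kept + 1):
        arg = 2.0 * np.pi * k * f * t
        rows.append(np.sin(arg))
        rows.append(np.cos(arg))
    return ReferenceTemplate(Y=np.vstack(rows), f=f, n_harmonics=kept, fs=fs)


# ---------------------------------------------------------------------------
# CCA


@dataclass
class CCAResult:
    rho: float
    w_p: np.ndarray    # channel weights (n_channels,)
    w_q: np.ndarray    # template weights (2 * n_harmonics,)


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def canonical_correlation(X: np.ndarray, Y: np.ndarray,
                          ridge: float = 1e-9) -> CCAResult:
    """Largest canonical correlation between row-spaces of ``X`` and ``Y``.

    Rows are centered internally.  The problem
    ``C_pq C_qq^-1 C_qp w = rho^2 C_pp w`` is solved as a generalized
    symmetric eigenvalue problem; a ridge of ``ridge * trace/dim`` on each
    auto-covariance guards against rank deficiency.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    nt = X.shape[1]
    if nt <= max(X.shape[0], Y.shape[0]):
        raise ValueError("need more samples than variables in either set")
    Xc, Yc = _center(X), _center(Y)
    if not np.any(Xc) or not np.any(Yc):
        raise DegenerateSignalError("constant input: canonical correlation "
                                    "undefined")
    cpp = Xc @ Xc.T / (nt - 1)
    cqq = Yc @ Yc.T / (nt - 1)
    cpq = Xc @ Yc.T / (nt - 1)
    cpp = cpp + ridge * np.trace(cpp) / cpp.shape[0] * np.eye(cpp.shape[0])
    cqq = cqq + ridge * np.trace(cqq) / cqq.shape[0] * np.eye(cqq.shape[0])
    try:
        a = cpq @ linalg.solve(cqq, cpq.T, assume_a="pos")
        eigvals, eigvecs = linalg.eigh(a, cpp)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"CCA failed despite ridge {ridge}: {exc}") from exc
    idx = int(np.argmax(eigvals))
    rho2 = float(np.clip(eigvals[idx], 0.0, None))
    w_p = eigvecs[:, idx]
    w_q = linalg.solve(cqq, cpq.T @ w_p, assume_a="pos")
    nq = np.linalg.norm(w_q)
    if nq > 0:
        w_q = w_q / nq
    return CCAResult(rho=float(np.sqrt(rho2)), w_p=w_p, w_q=w_q)


def _argmax_lowest_freq(frequencies: Sequence[float],
                        scores: np.ndarray) -> int:
    """Index of the max score; exact ties go to the lowest frequency."""
    scores = np.asarray(scores, dtype=float)
    best = np.flatnonzero(scores == scores.max())
    if len(best) > 1:
        logger.info("score tie between %s; choosing lowest frequency",
                    [frequencies[i] for i in best])
        best = best[np.argsort([frequencies[i] for i in best])]
    return int(best[0])


def cca_detect(X: np.ndarray, stimulus: StimulusSpec, n_harmonics: int = 4,
               fs: float = 256.0) -> tuple[float, np.ndarray]:
    """Standard CCA detection: argmax of rho(X, Y_f) over the candidates."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.empty(stimulus.n_targets)
    for i, f in enumerate(stimulus.frequencies):
        template = build_reference(f, n_harmonics, fs, X.shape[1])
        scores[i] = canonical_correlation(X, template.Y).rho
    idx = _argmax_lowest_freq(stimulus.frequencies, scores)
    return float(stimulus.frequencies[idx]), scores


# ---------------------------------------------------------------------------
# FBCCA


@dataclass
class FilterBankSpec:
    """Chebyshev-I band-pass filter bank with sub-band weights
    ``w(n) = n^-weight_a + weight_b``."""

    bands: tuple[tuple[float, float], ...] = (
        (6.0, 90.0), (9.0, 90.0), (13.0, 90.0), (18.0, 90.0), (22.0, 90.0))
    weight_a: float = 1.25
    weight_b: float = 0.25
    order: int = 4
    ripple_db: float = 0.5

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError("filter bank needs at least one band")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def weights(self) -> np.ndarray:
        n = np.arange(1, self.n_bands + 1, dtype=float)
        w = n ** (-self.weight_a) + self.weight_b
        if np.any(w <= 0):
            raise ValueError("sub-band weights must be positive")
        return w


@dataclass
class FBCCAScore:
    per_band: np.ndarray   # rho per sub-band
    combined: float        # sum_n w(n) rho_n^2


def design_filter_bank(spec: FilterBankSpec, fs: float) -> list[np.ndarray]:
    """Realize the filter bank as second-order sections, checked stable.

    High band edges beyond 95% of Nyquist are clipped (logged) so the bank
    stays usable at low sampling rates.
    """
    nyq = fs / 2.0
    sos_list = []
    for low, high in spec.bands:
        clipped_high = min(high, 0.95 * nyq)
        if clipped_high < high:
            logger.info("clipping band (%g, %g) Hz to (%g, %g) at fs=%g",
                        low, high, low, clipped_high, fs)
        if not (0.0 < low < clipped_high):
            raise ValueError(f"band ({low}, {high}) invalid at fs={fs}")
        sos = signal.cheby1(spec.order, spec.ripple_db, [low, clipped_high],
                            btype="bandpass", fs=fs, output="sos")
        _, poles, _ = signal.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"unstable filter for band ({low}, {high}); "
                             "try a lower order")
        sos_list.append(sos)
    return sos_list


def fbcca_score(X: np.ndarray, f: float, bank: FilterBankSpec,
                n_harmonics: int = 4, fs: float = 256.0,
                sos_list: list[np.ndarray] | None = None,
                subbands: np.ndarray | None = None) -> FBCCAScore:
    """Weighted sum of squared sub-band canonical correlations for one
    candidate frequency.

    ``sos_list``/``subbands`` allow reusing realized filters and filtered
    signals across candidate frequencies.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if subbands is None:
        if sos_list is None:
            sos_list = design_filter_bank(bank, fs)
        subbands = np.stack([signal.sosfiltfilt(sos, X, axis=1)
                             for sos in sos_list])
    template = build_reference(f, n_harmonics, fs, X.shape[1])
    rhos = np.array([canonical_correlation(xb, template.Y).rho
                     for xb in subbands])
    combined = float(np.sum(bank.weights * rhos ** 2))
    return FBCCAScore(per_band=rhos, combined=combined)


def fbcca_detect(X: np.ndarray, stimulus: StimulusSpec,
                 bank: FilterBankSpec | None = None, n_harmonics: int = 4,
                 fs: float = 256.0,
                 sos_list: list[np.ndarray] | None = None
                 ) -> tuple[float, np.ndarray]:
    """FBCCA detection: argmax of the combined sub-band score."""
    bank = bank if bank is not None else FilterBankSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if sos_list is None:
        sos_list = design_filter_bank(bank, fs)
    subbands = np.stack([signal.sosfiltfilt(sos, X, axis=1)
                         for sos in sos_list])
    scores = np.empty(stimulus.n_targets)
    for i, f in enumerate(stimulus.frequencies):
        scores[i] = fbcca_score(X, f, bank, n_harmonics, fs,
                                subbands=subbands).combined
    idx = _argmax_lowest_freq(stimulus.frequencies, scores)
    return float(stimulus.frequencies[idx]), scores


# ---------------------------------------------------------------------------
# MEC


@dataclass
class MECModel:
    """Fitted minimum-energy-combination model for one candidate frequency."""

    f: float
    G: np.ndarray          # (n_channels, 2 Nh) least-squares coefficients
    residual: np.ndarray   # (n_channels, n_samples) SSVEP-free part
    M: np.ndarray          # residual covariance (unnormalized)
    eigvals: np.ndarray    # ascending
    eigvecs: np.ndarray    # columns matching eigvals
    n_filters: int         # Nm
    W: np.ndarray          # (n_channels, Nm) spatial filters v_i / sqrt(l_i)


def mec_fit(X: np.ndarray, f: float, n_harmonics: int = 4, fs: float = 256.0,
            retention: float = 0.10) -> MECModel:
    """Fit the MEC spatial filters for candidate frequency ``f``.

    ``G`` solves ``X ~ G Y`` in least squares; the residual's covariance is
    eigendecomposed and the smallest-eigenvalue eigenvectors retained until
    their eigenvalues first exceed ``retention`` of the total residual
    energy (at least one).  Columns are scaled ``v_i / sqrt(lambda_i)`` so
    each filtered residual has unit energy.
    """
    X = _center(np.atleast_2d(np.asarray(X, dtype=float)))
    template = build_reference(f, n_harmonics, fs, X.shape[1])
    Y = template.Y
    if X.shape[1] <= Y.shape[0]:
        raise ValueError("need more samples than template rows")
    if not np.any(X):
        raise DegenerateSignalError("all-zero window")
    # G = X Y^+ : coefficients of the harmonic model per channel
    G, *_ = np.linalg.lstsq(Y.T, X.T, rcond=None)
    G = G.T
    residual = X - G @ Y
    M = residual @ residual.T
    eigvals, eigvecs = linalg.eigh(M)
    eigvals = np.clip(eigvals, 0.0, None)
    total = float(eigvals.sum())
    if total <= 1e-8 * float(np.sum(X * X)):
        logger.warning("MEC: residual nearly zero at f=%.4f Hz; "
                       "using a single unit filter", f)
        n_filters = 1
        W = eigvecs[:, :1].copy()
        return MECModel(f=f, G=G, residual=residual, M=M, eigvals=eigvals,
                        eigvecs=eigvecs, n_filters=n_filters, W=W)
    cumulative = np.cumsum(eigvals)
    n_filters = int(np.searchsorted(cumulative, retention * total) + 1)
    n_filters = max(1, min(n_filters, len(eigvals)))
    floor = 1e-12 * float(eigvals.max())
    scale = 1.0 / np.sqrt(np.maximum(eigvals[:n_filters], floor))
    W = eigvecs[:, :n_filters] * scale[None, :]
    return MECModel(f=f, G=G, residual=residual, M=M, eigvals=eigvals,
                    eigvecs=eigvecs, n_filters=n_filters, W=W)


def mec_power(X: np.ndarray, model: MECModel, template: ReferenceTemplate,
              literal: bool = False) -> float:
    """Average power of the spatially filtered signal at the template rows.

    ``p = 1/(Nm Nh) sum_i sum_j ( y_j . (X^T w_i) )^2`` — the squared
    projection of each filtered channel onto each sin/cos template row.
    ``literal=True`` sums the unsquared projections instead (the raw
    printed form of the power estimate, kept for comparison; it can cancel
    to ~0 for arbitrary phases and is not used for detection).
    """
    if abs(model.f - template.f) > 1e-9:
        raise ValueError(f"model fitted at {model.f} Hz but template is "
                         f"{template.f} Hz")
    X = _center(np.atleast_2d(np.asarray(X, dtype=float)))
    S = X.T @ model.W                    # (n_samples, Nm) filtered channels
    proj = template.Y @ S                # (2 Nh, Nm) projections
    nm = model.n_filters
    nh = template.n_harmonics
    if literal:
        return float(proj.sum() / (nm * nh))
    return float(np.sum(proj ** 2) / (nm * nh))


def mec_detect(X: np.ndarray, stimulus: StimulusSpec, n_harmonics: int = 4,
               fs: float = 256.0, retention: float = 0.10
               ) -> tuple[float, np.ndarray]:
    """MEC detection: fit filters and score power per candidate, argmax."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.empty(stimulus.n_targets)
    for i, f in enumerate(stimulus.frequencies):
        model = mec_fit(X, f, n_harmonics, fs, retention=retention)
        template = build_reference(f, n_harmonics, fs, X.shape[1])
        scores[i] = mec_power(X, model, template)
    idx = _argmax_lowest_freq(stimulus.frequencies, scores)
    return float(stimulus.frequencies[idx]), scores


# ---------------------------------------------------------------------------
# uniform detector API


@dataclass
class Detector:
    """Fit-free detector with a uniform ``detect(X) -> (f, scores)`` API."""

    name: str
    stimulus: StimulusSpec
    n_harmonics: int = 4
    fs: float = 256.0
    bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    retention: float = 0.10
    _sos: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.name not in ("cca", "fbcca", "mec"):
            raise ValueError(f"unknown detector {self.name!r}")
        if self.name == "fbcca":
            self._sos = design_filter_bank(self.bank, self.fs)

    def detect(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        if self.name == "cca":
            return cca_detect(X, self.stimulus, self.n_harmonics, self.fs)
        if self.name == "fbcca":
            return fbcca_detect(X, self.stimulus, self.bank,
                                self.n_harmonics, self.fs, sos_list=self._sos)
        return mec_detect(X, self.stimulus, self.n_harmonics, self.fs,
                          retention=self.retention)

    def __call__(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        return self.detect(X)


DETECTOR_NAMES = ("cca", "fbcca", "mec")
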