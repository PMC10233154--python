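"""Session containers, preprocessing and epoch extraction.

A :class:`Recording` holds one run of continuous multi-channel EEG together
with an event-marker track encoding the five trial phases (fixation, target
presentation, preparation, stimulation, rest).  Three epoch kinds are cut
around the stimulation onset:

``stimulation``
    the full 5-s stimulation phase, starting at onset (``t0 = 0``);
``no_stimulation``
    the 5 s immediately preceding onset (fixation + target + preparation);
``detection``
    a 6-s window starting 1 s before onset (``t0 = -1``), the input of the
    sliding-window pseudo-online assessment.

The default on-disk dialect is a delimited-text sample matrix plus a JSON
sidecar carrying sampling rate, channel names and markers; it round-trips
losslessly.  EDF files are readable through the optional :mod:`mne` adapter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2")

PARADIGMS = ("OOR", "OOS", "CBR", "CBS")

EPOCH_KINDS = ("stimulation", "no_stimulation", "detection")


class MarkerCode(IntEnum):
    """Event codes of the five trial phases."""

    FIXATION = 1
    TARGET = 2       # payload = target index 0..n_targets-1
    PREPARATION = 3
    STIMULATION = 4
    REST = 5


class Marker(NamedTuple):
    sample: int
    code: int
    payload: int | None = None


class FormatError(ValueError):
    """Raised when a recording file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a recording violates its structural invariants."""


@dataclass
class Recording:
    """Continuous multi-channel EEG with a marker track.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample matrix in microvolts, channel-major.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        Ordered channel labels; length must equal ``data.shape[0]``.
    markers : list of Marker
        Phase events as ``(sample_index, code, payload)``, nondecreasing in
        sample index.
    paradigm : str
        Visual paradigm of the run (OOR/OOS/CBR/CBS) or "" if unknown.
    subject_id : str
    stim_frequencies : tuple of float, optional
        Stimulation frequencies indexed by the target-marker payload; needed
        to label epochs with their target frequency.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    markers: list[Marker] = field(default_factory=list)
    paradigm: str = ""
    subject_id: str = ""
    stim_frequencies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D (channels x samples) array")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        self.markers = [Marker(int(s), int(c), None if p is None else int(p))
                        for s, c, p in self.markers]
        n_total = self.data.shape[1]
        last = -1
        for m in self.markers:
            if m.sample < 0 or m.sample >= n_total:
                raise ValidationError(f"marker sample {m.sample} outside recording")
            if m.sample < last:
                raise ValidationError("marker samples must be nondecreasing")
            last = m.sample

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One trial's windowed signal matrix with its label.

    ``t0`` is the epoch start relative to stimulation onset in seconds
    (0 for stimulation epochs, -1 for detection epochs, -5 for
    no-stimulation epochs).
    """

    X: np.ndarray
    fs: float
    t0: float
    kind: str
    target_frequency: float
    paradigm: str = ""
    trial_index: int = -1
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.kind not in EPOCH_KINDS:
            raise ValidationError(f"unknown epoch kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# file I/O: text dialect (default) and EDF read adapter


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as delimited text plus a JSON sidecar.

    ``path`` names the sample-matrix file (one row per channel, tab
    separated, ``%.17g`` so that round-tripping is exact); the sidecar with
    sampling rate, channels and markers is written next to it with a
    ``.json`` suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "markers": [[m.sample, m.code, m.payload] for m in rec.markers],
        "paradigm": rec.paradigm,
        "subject_id": rec.subject_id,
        "stim_frequencies": (None if rec.stim_frequencies is None
                             else list(rec.stim_frequencies)),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    try:
        markers = [Marker(int(s), int(c), None if p is None else int(p))
                   for s, c, p in meta["markers"]]
        rec = Recording(
            data=data,
            fs=float(meta["fs"]),
            channel_names=tuple(meta["channel_names"]),
            markers=markers,
            paradigm=meta.get("paradigm", ""),
            subject_id=meta.get("subject_id", ""),
            stim_frequencies=(None if meta.get("stim_frequencies") is None
                              else tuple(meta["stim_frequencies"])),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    return rec


def _read_edf(path: Path) -> Recording:
    """EDF adapter (read-only); annotations become markers when their
    descriptions are integer codes, optionally ``code:payload``."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise FormatError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    markers: list[Marker] = []
    for onset, _dur, desc in zip(raw.annotations.onset,
                                 raw.annotations.duration,
                                 raw.annotations.description):
        parts = str(desc).split(":")
        try:
            code = int(parts[0])
            payload = int(parts[1]) if len(parts) > 1 else None
        except ValueError:
            continue
        markers.append(Marker(int(round(onset * raw.info["sfreq"])), code, payload))
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_names=tuple(raw.ch_names), markers=markers)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(rec: Recording,
               band: tuple[float, float] = (0.5, 60.0),
               notch: float | None = 60.0,
               order: int = 4,
               notch_q: float = 30.0) -> Recording:
    """Zero-phase band-pass plus notch filtering, per channel.

    A 4th-order Butterworth band-pass applied forward-backward (via
    ``sosfiltfilt``) and an IIR notch at the power-line frequency.  Markers
    and metadata are unchanged.  Set ``notch=None`` to skip the notch stage
    (e.g. when the band already excludes it).
    """
    low, high = band
    nyq = rec.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2 = {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        if not (0.0 < notch < nyq):
            raise ValueError(f"notch frequency {notch} outside (0, fs/2)")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# epoch extraction


def _iter_trials(rec: Recording):
    """Group the marker track into trials; yields dict code -> Marker."""
    trial: dict[int, Marker] = {}
    for m in rec.markers:
        if m.code == MarkerCode.FIXATION:
            if trial:
                yield trial
            trial = {}
        trial[m.code] = m
    if trial:
        yield trial


def extract_epochs(rec: Recording, kind: str,
                   stim_frequencies: Sequence[float] | None = None
                   ) -> list[Epoch]:
    """Cut one epoch of the requested kind per complete trial.

    Trials missing any of the required phase markers, or whose epoch window
    falls outside the recording, are skipped with a logged warning.  The
    target frequency is looked up from the target-presentation marker
    payload in ``stim_frequencies`` (falling back to the recording's own
    ``stim_frequencies`` metadata).
    """
    if kind not in EPOCH_KINDS:
        raise ValueError(f"unknown epoch kind {kind!r}; expected one of {EPOCH_KINDS}")
    freqs = stim_frequencies if stim_frequencies is not None else rec.stim_frequencies
    if freqs is None:
        raise ValueError("stimulation frequencies unknown: pass stim_frequencies "
                         "or use a recording that carries them")
    fs = rec.fs
    epochs: list[Epoch] = []
    n_skipped = 0
    for trial_index, trial in enumerate(_iter_trials(rec)):
        needed = (MarkerCode.TARGET, MarkerCode.STIMULATION, MarkerCode.REST)
        if any(code not in trial for code in needed):
            n_skipped += 1
            logger.warning("trial %d skipped: missing phase marker", trial_index)
            continue
        onset = trial[MarkerCode.STIMULATION].sample
        rest = trial[MarkerCode.REST].sample
        stim_len = rest - onset
        if kind == "stimulation":
            start, stop, t0 = onset, rest, 0.0
        elif kind == "no_stimulation":
            # fixation + target presentation + preparation, ending at onset
            fix = trial.get(MarkerCode.FIXATION)
            start = fix.sample if fix is not None else onset - stim_len
            stop, t0 = onset, (start - onset) / fs
        else:  # detection
            start = onset - int(round(1.0 * fs))
            stop, t0 = rest, -1.0
        if start < 0 or stop > rec.n_samples or stop <= start:
            n_skipped += 1
            logger.warning("trial %d skipped: epoch window outside recording",
                           trial_index)
            continue
        target_index = trial[MarkerCode.TARGET].payload
        if target_index is None or not (0 <= target_index < len(freqs)):
            n_skipped += 1
            logger.warning("trial %d skipped: invalid target payload %r",
                           trial_index, target_index)
            continue
        epochs.append(Epoch(
            X=rec.data[:, start:stop].copy(),
            fs=fs,
            t0=t0,
            kind=kind,
            target_frequency=float(freqs[target_index]),
            paradigm=rec.paradigm,
            trial_index=trial_index,
            channel_names=rec.channel_names,
        ))
    if n_skipped:
        logger.warning("%d of %d trials skipped during epoch extraction",
                       n_skipped, n_skipped + len(epochs))
    return epochs
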