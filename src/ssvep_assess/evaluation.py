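"""Pseudo-online assessment: sliding-window detection and DA/DT/ITR metrics.

Each 6-s detection epoch (1 s pre-onset + 5 s stimulation) is scanned with
1-s windows shifted by 0.05 s; a trial's frequency is decided when three
consecutive windows agree, and the detection time (DT) is the end time of
the third agreeing window, measured from stimulation onset.  Windows ending
at or before onset are scored but excluded from the agreement counter,
since DT should reflect post-onset evidence only.  If no triple ever
agrees, the final decision falls back to the last window and DT is the full
stimulation length; such trials count as incorrect by default.

Detection accuracy (DA) is the fraction of correctly decided trials;
the information transfer rate (ITR, bits/min) is

    ITR = (60/DT) [ log2 N + DA log2 DA + (1-DA) log2((1-DA)/(N-1)) ]

clamped to zero at or below the 1/N chance level.  Cross-condition
statistics use a Kruskal-Wallis omnibus test with rank-based pairwise
follow-ups under Holm correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ssvep_assess.detectors import DETECTOR_NAMES, Detector, FilterBankSpec
from ssvep_assess.recording_io import Epoch, Recording, extract_epochs, preprocess

logger = logging.getLogger(__name__)

DetectorFn = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters of the pseudo-online detector."""

    t_win: float = 1.0
    t_shift: float = 0.05
    consecutive_required: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.t_shift <= self.t_win):
            raise ValueError("need 0 < t_shift <= t_win")
        if self.consecutive_required < 1:
            raise ValueError("consecutive_required must be >= 1")


@dataclass
class DetectionTrace:
    """Per-window decisions of one trial plus the final decision."""

    window_end_times: np.ndarray   # s, relative to stimulation onset
    decisions: np.ndarray          # frequency per window
    final_frequency: float
    detection_time: float          # s; stimulation length if no triple agreed
    detected_by_rule: bool
    target_frequency: float
    correct: bool
    paradigm: str = ""
    trial_index: int = -1


def sliding_trace(epoch: Epoch, detector: DetectorFn,
                  cfg: WindowConfig | None = None,
                  rule: str = "target_confirmation") -> DetectionTrace:
    """Run a detector over every sliding window of a detection epoch.

    Windows start at ``epoch.t0`` and advance by ``t_shift`` while they fit
    inside the epoch; every window is scored, but the agreement counter
    considers only windows whose end time is after stimulation onset
    (t = 0), so DT measures post-onset evidence.

    Two decision rules are provided:

    ``"target_confirmation"`` (default)
        the trial counts as detected when ``consecutive_required`` windows
        in a row pick the trial's true stimulation frequency; DT is the end
        time of the confirming window.  This is what "number of correct
        detections" counts in the accuracy metric: with heavily overlapping
        windows the per-window decisions are strongly correlated, so
        requiring confirmation of the attended frequency measures when the
        stimulation evidence takes over from the background.
    ``"first_agreement"``
        the first triple of *any* agreeing candidate decides the trial
        (correct or not).  With a 0.05-s shift consecutive windows share
        95% of their samples, so this rule tends to latch onto the
        background-driven decision within the first few post-onset windows;
        it is kept for comparison.

    If the rule never fires, the final decision falls back to the last
    window, DT is the end of the stimulation phase, and the trace is marked
    undetected.
    """
    cfg = cfg if cfg is not None else WindowConfig()
    if rule not in ("target_confirmation", "first_agreement"):
        raise ValueError(f"unknown decision rule {rule!r}")
    if epoch.kind != "detection":
        raise ValueError(f"sliding_trace needs a detection epoch, got "
                         f"{epoch.kind!r}")
    if epoch.duration_s < cfg.t_win:
        raise ValueError("epoch shorter than one window")
    fs = epoch.fs
    n_win = int(round(cfg.t_win * fs))
    epoch_end = epoch.t0 + epoch.duration_s
    n_windows = int(math.floor(
        (epoch.duration_s - cfg.t_win) / cfg.t_shift + 1e-9)) + 1
    end_times = np.empty(n_windows)
    decisions = np.empty(n_windows)
    final_frequency = math.nan
    detection_time = math.nan
    detected = False
    run_freq, run_len = math.nan, 0
    for k in range(n_windows):
        t_start = epoch.t0 + k * cfg.t_shift
        start = int(round((t_start - epoch.t0) * fs))
        f_hat, _ = detector(epoch.X[:, start:start + n_win])
        end_times[k] = t_start + cfg.t_win
        decisions[k] = f_hat
        if detected or end_times[k] <= 1e-9:
            continue  # pre-onset windows don't feed the agreement counter
        if rule == "target_confirmation" and not math.isclose(
                f_hat, epoch.target_frequency, rel_tol=1e-9):
            run_freq, run_len = math.nan, 0
            continue
        if run_len > 0 and math.isclose(f_hat, run_freq):
            run_len += 1
        else:
            run_freq, run_len = f_hat, 1
        if run_len >= cfg.consecutive_required:
            final_frequency = f_hat
            detection_time = end_times[k]
            detected = True
    if not detected:
        final_frequency = float(decisions[-1])
        detection_time = epoch_end
        logger.debug("trial %d: rule %s did not fire", epoch.trial_index, rule)
    correct = math.isclose(final_frequency, epoch.target_frequency,
                           rel_tol=1e-9)
    return DetectionTrace(
        window_end_times=end_times, decisions=decisions,
        final_frequency=final_frequency, detection_time=detection_time,
        detected_by_rule=detected, target_frequency=epoch.target_frequency,
        correct=correct, paradigm=epoch.paradigm,
        trial_index=epoch.trial_index)


def detection_accuracy(traces: Sequence[DetectionTrace],
                       count_undetected_as_incorrect: bool = True) -> float:
    """Fraction of correct detections, N_detects / N_trials.

    Trials where the 3-consecutive rule never fired count as incorrect by
    default, even if the fallback (last-window) decision happened to match.
    """
    if not traces:
        raise ValueError("no traces")
    hits = sum(t.correct and (t.detected_by_rule
                              or not count_undetected_as_incorrect)
               for t in traces)
    return hits / len(traces)


def epoch_accuracy(epochs: Sequence[Epoch], detector: DetectorFn) -> float:
    """Trial-level DA: one whole-epoch detection per trial."""
    if not epochs:
        raise ValueError("no epochs")
    hits = 0
    for e in epochs:
        f_hat, _ = detector(e.X)
        hits += math.isclose(f_hat, e.target_frequency, rel_tol=1e-9)
    return hits / len(epochs)


def itr(da: float, dt_s: float, n_targets: int = 5) -> float:
    """Information transfer rate in bits per minute.

    ``s = 60 / DT`` decisions per minute times the per-decision bit rate;
    accuracies at or below the 1/N chance level yield 0, and DA = 1 uses the
    ``0 log 0 = 0`` limit.
    """
    if not (0.0 <= da <= 1.0):
        raise ValueError("DA must be in [0, 1]")
    if dt_s <= 0:
        raise ValueError("DT must be positive")
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    if da <= 1.0 / n_targets:
        return 0.0
    s = 60.0 / dt_s
    bits = math.log2(n_targets)
    bits += da * math.log2(da)
    if da < 1.0:
        bits += (1.0 - da) * math.log2((1.0 - da) / (n_targets - 1))
    return s * bits


# ---------------------------------------------------------------------------
# cross-condition statistics


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    pvalue: float           # Holm-adjusted
    significance_tier: float | None   # 0.001 / 0.01 / 0.05 or None


@dataclass
class ComparisonReport:
    """Kruskal-Wallis omnibus plus rank-based pairwise follow-ups."""

    H: float
    pvalue: float
    alpha: float
    groups: tuple[str, ...]
    pairwise: list[PairwiseResult]

    @property
    def significant(self) -> bool:
        return self.pvalue <= self.alpha

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [p.pair for p in self.pairwise
                if p.significance_tier is not None]


def compare_conditions(metric_samples: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> ComparisonReport:
    """Omnibus + pairwise comparison of a metric across conditions.

    Kruskal-Wallis across all groups; pairwise Mann-Whitney U follow-ups
    with Holm family-wise correction, reported at the 0.001 / 0.01 / 0.05
    tiers.  Degenerate input (fewer than two groups, groups with fewer than
    two samples, or all values identical) raises ``ValueError``.
    """
    names = tuple(metric_samples.keys())
    groups = [np.asarray(metric_samples[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two samples")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: rank test undefined")
    h_stat, p = stats.kruskal(*groups)
    pairs = list(itertools.combinations(range(len(names)), 2))
    raw = []
    for i, j in pairs:
        res = stats.mannwhitneyu(groups[i], groups[j],
                                 alternative="two-sided")
        raw.append((float(res.statistic), float(res.pvalue)))
    # Holm step-down correction
    order = np.argsort([pv for _, pv in raw])
    m = len(raw)
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * raw[idx][1])
        running_max = max(running_max, adj)
        adjusted[idx] = running_max
    pairwise = []
    for (i, j), (u_stat, _), adj in zip(pairs, raw, adjusted):
        tier = next((t for t in (0.001, 0.01, 0.05) if adj <= t), None)
        if tier is not None and tier > alpha:
            tier = None
        pairwise.append(PairwiseResult(pair=(names[i], names[j]),
                                       statistic=u_stat, pvalue=adj,
                                       significance_tier=tier))
    return ComparisonReport(H=float(h_stat), pvalue=float(p), alpha=alpha,
                            groups=names, pairwise=pairwise)


# ---------------------------------------------------------------------------
# full factorial assessment


def run_assessment(recordings: Mapping[str, Recording],
                   methods: Sequence[str] = DETECTOR_NAMES,
                   cfg: WindowConfig | None = None,
                   n_harmonics: int = 4,
                   bank: FilterBankSpec | None = None,
                   preprocess_band: tuple[float, float] | None = (0.5, 60.0),
                   notch: float | None = 60.0,
                   dt_include_undetected: bool = True,
                   rule: str = "target_confirmation"
                   ) -> pd.DataFrame:
    """Method x paradigm x frequency grid of DA / DT / ITR.

    Each recording is band-pass + notch preprocessed (set
    ``preprocess_band=None`` to skip), cut into 6-s detection epochs and
    scanned per method.  Rows are keyed by (method, paradigm, frequency);
    ``dt_include_undetected`` controls whether trials without a triple
    agreement (DT = stimulation length) enter the DT average.
    """
    cfg = cfg if cfg is not None else WindowConfig()
    bank = bank if bank is not None else FilterBankSpec()
    rows = []
    for paradigm, rec in recordings.items():
        if preprocess_band is not None:
            rec = preprocess(rec, band=preprocess_band, notch=notch)
        epochs = extract_epochs(rec, "detection")
        if not epochs:
            raise ValueError(f"recording {paradigm!r} yielded no epochs")
        freqs = sorted({e.target_frequency for e in epochs})
        stimulus = _stimulus_from_recording(rec)
        for method in methods:
            detector = Detector(name=method, stimulus=stimulus,
                                n_harmonics=n_harmonics, fs=rec.fs, bank=bank)
            traces = [sliding_trace(e, detector, cfg, rule=rule)
                      for e in epochs]
            for f in freqs:
                sub = [t for t in traces
                       if math.isclose(t.target_frequency, f)]
                da = detection_accuracy(sub)
                dts = [t.detection_time for t in sub
                       if dt_include_undetected or t.detected_by_rule]
                dt_mean = float(np.mean(dts)) if dts else math.nan
                dt_sd = float(np.std(dts, ddof=1)) if len(dts) > 1 else math.nan
                rate = (itr(da, dt_mean, stimulus.n_targets)
                        if dts else math.nan)
                rows.append({
                    "method": method, "paradigm": paradigm, "frequency": f,
                    "DA": da, "DT_mean": dt_mean, "DT_sd": dt_sd,
                    "ITR": rate, "n_trials": len(sub),
                    "n_detects": sum(t.correct and t.detected_by_rule
                                     for t in sub),
                })
    return pd.DataFrame(rows)


def _stimulus_from_recording(rec: Recording):
    from ssvep_assess.synthetic_data import StimulusSpec
    if rec.stim_frequencies is None:
        raise ValueError("recording carries no stimulation frequencies")
    paradigm = rec.paradigm if rec.paradigm else "OOR"
    return StimulusSpec(paradigm=paradigm,
                        frequencies=tuple(rec.stim_frequencies),
                        n_targets=len(rec.stim_frequencies))
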