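"""Epoching, baseline correction, ERP averaging and difference scores.

Stimulus-locked epochs span -100..1000 ms (half-open in samples) around
each marker; the 100 ms pre-stimulus mean is the baseline.  Mean
amplitudes are scored at Fz with inclusive window endpoints: N2 over
300-400 ms (negative, larger on NoGo) and P3 over 480-600 ms (positive,
larger on NoGo).  The inhibition-specific difference scores are
NoGo - Go per emotion (N2d, P3d); a second family subtracts neutral from
angry/happy within each condition to remove face-processing activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emogo.core import CONDITIONS, EMOTIONS, ms_to_sample
from emogo.preprocess import CleanRecording

N2_WINDOW_MS = (300.0, 400.0)
P3_WINDOW_MS = (480.0, 600.0)
SCORING_CHANNEL = "Fz"


@dataclass
class EpochSet:
    """Baseline-correctable stimulus-locked segments with metadata.

    ``data`` is (n_epochs, n_channels, n_samples); ``times_ms[i]`` is the
    latency of sample i relative to stimulus onset; ``meta`` has one row
    per retained epoch (trial_id, condition, emotion, correct, rt_ms);
    ``drop_log`` records every dropped trial with the rule that fired.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    meta: pd.DataFrame
    drop_log: pd.DataFrame
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    baseline_corrected: bool = False

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None


def epoch(clean: CleanRecording, trial_log: pd.DataFrame,
          tmin_ms: float = -100.0, tmax_ms: float = 1000.0,
          anticipatory_rt_ms: float = 200.0) -> EpochSet:
    """Cut epochs around every event, applying the exclusion rules.

    Dropped (with logged reason): practice trials; trials whose response
    was anticipatory (RT < 200 ms); epochs overlapping any bad span;
    epochs extending past the recording edge.  An empty result is returned
    explicitly (never an error) so callers can flag the subject.
    """
    raw = clean.raw
    rate = raw.rate
    n_samp = ms_to_sample(tmax_ms - tmin_ms, rate)
    offset = ms_to_sample(tmin_ms, rate)
    times = (np.arange(n_samp) + offset) * 1000.0 / rate

    log_rows, kept, meta_rows = [], [], []
    tl = {int(rec["trial_id"]): rec for rec in trial_log.to_dict("records")}
    for ev in raw.events:
        trial = tl[ev.trial_id]
        start = ev.sample + offset
        end = start + n_samp
        rt = trial["rt_ms"]
        responded = bool(trial["responded"]) if pd.notna(trial["responded"]) else False
        if ev.is_practice or bool(trial["is_practice"]):
            reason = "practice"
        elif responded and pd.notna(rt) and rt < anticipatory_rt_ms:
            reason = "anticipatory"
        elif start < 0 or end > raw.n_samples:
            reason = "bounds"
        elif any(s.overlaps(start, end) for s in clean.bad_spans):
            reason = next(s.kind for s in clean.bad_spans if s.overlaps(start, end))
        else:
            reason = None
        if reason is not None:
            log_rows.append(dict(trial_id=ev.trial_id, reason=reason))
            continue
        kept.append(raw.data[:, start:end])
        meta_rows.append(dict(trial_id=ev.trial_id, condition=ev.condition,
                              emotion=ev.emotion,
                              correct=bool(trial["correct"]) if pd.notna(trial["correct"]) else False,
                              rt_ms=rt))
    data = np.stack(kept) if kept else np.empty((0, raw.n_channels, n_samp))
    return EpochSet(
        data=data, times_ms=times, channels=raw.layout.retained,
        meta=pd.DataFrame(meta_rows, columns=["trial_id", "condition", "emotion", "correct", "rt_ms"]),
        drop_log=pd.DataFrame(log_rows, columns=["trial_id", "reason"]),
        baseline_ms=(tmin_ms, 0.0),
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    lo, hi = epochs.baseline_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data=epochs.data - base, times_ms=epochs.times_ms,
                    channels=epochs.channels, meta=epochs.meta,
                    drop_log=epochs.drop_log, baseline_ms=epochs.baseline_ms,
                    baseline_corrected=True)


def average_erp(epochs: EpochSet, condition: str, emotion: str,
                correct_only: bool = True) -> tuple[np.ndarray | None, int]:
    """Per-sample mean waveform over the selected epochs, with its n.

    Returns ``(None, 0)`` when no epoch matches (the cell is missing).
    """
    sel = (epochs.meta["condition"] == condition) & (epochs.meta["emotion"] == emotion)
    if correct_only:
        sel &= epochs.meta["correct"].astype(bool)
    idx = np.flatnonzero(sel.to_numpy())
    if len(idx) == 0:
        return None, 0
    return epochs.data[idx].mean(axis=0), int(len(idx))


def mean_amplitude(waveform: np.ndarray, times_ms: np.ndarray,
                   window_ms: tuple[float, float], channels: tuple[str, ...],
                   channel: str = SCORING_CHANNEL) -> float:
    """Mean µV of one channel over a latency window (inclusive endpoints)."""
    try:
        ci = channels.index(channel)
    except ValueError:
        raise KeyError(f"channel {channel!r} absent") from None
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError("scoring window contains no samples")
    return float(waveform[ci, mask].mean())


@dataclass
class ErpSummary:
    """Per-subject mean amplitudes and difference scores.

    ``cells``: one row per condition x emotion with n2_uv, p3_uv, n_valid.
    ``diffs``: per emotion N2d/P3d (NoGo - Go).  ``contrasts``: per emotion
    in {angry, happy} the emotion-minus-neutral values per condition and
    their NoGo - Go contrast.  Missing cells propagate as NaN.
    """

    cells: pd.DataFrame
    diffs: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None


def summarize_erp(epochs: EpochSet, correct_only: bool = True,
                  n2_window: tuple[float, float] = N2_WINDOW_MS,
                  p3_window: tuple[float, float] = P3_WINDOW_MS,
                  channel: str = SCORING_CHANNEL) -> ErpSummary:
    """Score N2/P3 mean amplitudes for every condition x emotion cell."""
    if not epochs.baseline_corrected:
        epochs = baseline_correct(epochs)
    rows = []
    for cond in CONDITIONS:
        for emo in EMOTIONS:
            wave, n = average_erp(epochs, cond, emo, correct_only=correct_only)
            if wave is None:
                rows.append(dict(condition=cond, emotion=emo, n2_uv=np.nan,
                                 p3_uv=np.nan, n_valid=0))
            else:
                rows.append(dict(
                    condition=cond, emotion=emo,
                    n2_uv=mean_amplitude(wave, epochs.times_ms, n2_window,
                                         epochs.channels, channel),
                    p3_uv=mean_amplitude(wave, epochs.times_ms, p3_window,
                                         epochs.channels, channel),
                    n_valid=n))
    return ErpSummary(cells=pd.DataFrame(rows))


def difference_scores(summary: ErpSummary) -> ErpSummary:
    """Augment a summary with NoGo-Go and emotion-minus-neutral scores."""
    cells = summary.cells.set_index(["condition", "emotion"])

    def amp(cond: str, emo: str, comp: str) -> float:
        try:
            return float(cells.loc[(cond, emo), comp])
        except KeyError:
            return np.nan

    diffs = pd.DataFrame([
        dict(emotion=emo,
             n2d_uv=amp("NoGo", emo, "n2_uv") - amp("Go", emo, "n2_uv"),
             p3d_uv=amp("NoGo", emo, "p3_uv") - amp("Go", emo, "p3_uv"))
        for emo in EMOTIONS
    ])

    rows = []
    for emo in ("angry", "happy"):
        for comp in ("n2_uv", "p3_uv"):
            go = amp("Go", emo, comp) - amp("Go", "neutral", comp)
            nogo = amp("NoGo", emo, comp) - amp("NoGo", "neutral", comp)
            rows.append(dict(emotion=emo, component=comp.replace("_uv", ""),
                             go_minus_neutral=go, nogo_minus_neutral=nogo,
                             nogo_minus_go=nogo - go))
    return ErpSummary(cells=summary.cells, diffs=diffs, contrasts=pd.DataFrame(rows))


@dataclass(frozen=True)
class QcDecision:
    """Subject-level inclusion decision with the rules that fired."""

    included_behavior: bool
    included_erp: bool
    reasons: tuple[str, ...]


def subject_qc(summary: ErpSummary, overall_accuracy: float,
               min_trials: int = 3, min_accuracy: float = 50.0) -> QcDecision:
    """Apply the accuracy<50% and minimum-valid-trials exclusion rules.

    A subject failing the accuracy rule is excluded from all analyses;
    a subject with any condition x emotion cell below ``min_trials`` valid
    epochs is excluded from ERP analyses only.
    """
    reasons: list[str] = []
    ok_acc = overall_accuracy >= min_accuracy
    if not ok_acc:
        reasons.append(f"accuracy {overall_accuracy:.1f}% < {min_accuracy:.0f}%")
    ok_trials = bool((summary.cells["n_valid"] >= min_trials).all())
    if not ok_trials:
        bad = summary.cells.loc[summary.cells["n_valid"] < min_trials,
                                ["condition", "emotion", "n_valid"]]
        for _, r in bad.iterrows():
            reasons.append(f"{r.condition}/{r.emotion}: {int(r.n_valid)} valid trials "
                           f"< {min_trials}")
    return QcDecision(included_behavior=ok_acc,
                      included_erp=ok_acc and ok_trials,
                      reasons=tuple(reasons))
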