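"""Continuous-EEG cleaning chain.

Fixed pipeline order: band-pass 0.3-100 Hz -> average re-reference ->
+/-200 µV threshold artifact marking -> blink detection at Fp1/Fp2 ->
30 Hz low-pass for ERP construction.  All filters are zero-phase
(4th-order Butterworth applied forward-backward), so component latencies
are preserved.  "Exclusion" of artifacts is implemented as span marking;
epochs overlapping a marked span are dropped at epoching time, which
keeps continuous timing intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from emogo.core import RawRecording, Span, merge_spans, ms_to_sample


@dataclass
class CleanRecording:
    """A recording plus the bad spans found on it."""

    raw: RawRecording
    bad_spans: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bad_spans = merge_spans(self.bad_spans) if self.bad_spans else []

    def add_spans(self, spans: list[Span]) -> "CleanRecording":
        keep = list(self.bad_spans) + list(spans)
        return CleanRecording(raw=self.raw, bad_spans=keep)


def _sos_filtfilt(raw: RawRecording, sos: np.ndarray, log: dict) -> RawRecording:
    out = signal.sosfiltfilt(sos, raw.data, axis=1)
    return raw.copy_with(out, extra_log=log)


def bandpass(raw: RawRecording, low_hz: float = 0.3, high_hz: float = 100.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass."""
    nyq = raw.rate / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=raw.rate, output="sos")
    return _sos_filtfilt(raw, sos, dict(filter="bandpass", low_hz=low_hz,
                                        high_hz=high_hz, order=order, zero_phase=True))


def lowpass_for_erp(raw: RawRecording, cutoff_hz: float = 30.0, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth low-pass applied before epoching."""
    if cutoff_hz >= raw.rate / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {raw.rate / 2} Hz")
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=raw.rate, output="sos")
    return _sos_filtfilt(raw, sos, dict(filter="lowpass", cutoff_hz=cutoff_hz,
                                        order=order, zero_phase=True))


def average_reference(raw: RawRecording) -> RawRecording:
    """Re-reference every channel to the mean of all retained channels."""
    if raw.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = raw.data - raw.data.mean(axis=0, keepdims=True)
    return raw.copy_with(out, extra_log=dict(filter="average_reference"))


def mark_threshold_artifacts(raw: RawRecording, limit_uv: float = 200.0,
                             pad_ms: float = 100.0) -> CleanRecording:
    """Mark every sample exceeding +/-limit on any channel as bad.

    Contiguous runs become spans padded by ``pad_ms`` on each side and
    merged.
    """
    if limit_uv <= 0:
        raise ValueError("limit must be positive")
    bad = np.any(np.abs(raw.data) > limit_uv, axis=0)
    spans = [Span(s, e, "threshold")
             for s, e in _runs(bad, pad=ms_to_sample(pad_ms, raw.rate), n=raw.n_samples)]
    return CleanRecording(raw=raw, bad_spans=spans)


def _runs(mask: np.ndarray, pad: int, n: int) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in ``mask``, padded and clipped."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return [(max(0, int(s) - pad), min(n, int(e) + pad)) for s, e in zip(starts, ends)]


@dataclass(frozen=True)
class BlinkEvent:
    """A detected blink: peak location and measured features."""

    channel: str
    peak_sample: int
    onset: int          # preceding 10%-of-peak crossing
    offset: int         # following 10%-of-peak crossing
    amplitude_uv: float
    rise_ms: float
    fall_ms: float


def _blink_candidates(x: np.ndarray, rate: float, prescreen_uv: float,
                      min_amp_uv: float, min_rise_ms: float, min_fall_ms: float,
                      channel: str, polarity: int) -> list[BlinkEvent]:
    """Candidate blink deflections of one polarity on one frontal channel.

    Amplitude is measured against a local median baseline (+/-1.5 s around
    the peak) so slow background drift neither masks nor fakes a blink;
    rise/fall run from the preceding/following crossing of baseline + 10%
    of the peak-to-baseline amplitude.
    """
    sig = polarity * x
    half_win = ms_to_sample(1500, rate)
    # candidate peaks: local extrema above the pre-screen, separated by >=100 ms
    peaks, _ = signal.find_peaks(sig, height=prescreen_uv,
                                 distance=max(1, ms_to_sample(100, rate)))
    found: list[BlinkEvent] = []
    for p in peaks:
        lo, hi = max(0, p - half_win), min(len(sig), p + half_win)
        baseline = float(np.median(sig[lo:hi]))
        amp = sig[p] - baseline
        if amp <= min_amp_uv:
            continue
        thr = baseline + 0.1 * amp
        before = np.flatnonzero(sig[:p] < thr)
        after = np.flatnonzero(sig[p:] < thr)
        onset = int(before[-1]) + 1 if len(before) else 0
        offset = int(p + after[0]) if len(after) else len(sig)
        rise_ms = (p - onset) * 1000.0 / rate
        fall_ms = (offset - p) * 1000.0 / rate
        if rise_ms > min_rise_ms and fall_ms > min_fall_ms:
            found.append(BlinkEvent(channel=channel, peak_sample=int(p), onset=onset,
                                    offset=offset, amplitude_uv=float(amp),
                                    rise_ms=rise_ms, fall_ms=fall_ms))
    return found


def detect_blinks(clean: CleanRecording, channels: tuple[str, ...] = ("Fp1", "Fp2"),
                  min_rise_ms: float = 100.0, min_fall_ms: float = 150.0,
                  min_amp_uv: float = 125.0, prescreen_uv: float = 40.0,
                  both_polarities: bool = True,
                  smooth_hz: float = 15.0) -> tuple[CleanRecording, list[BlinkEvent]]:
    """Detect blinks on the frontal channels and mark them as bad spans.

    A candidate deflection is flagged as a blink iff rise time > 100 ms,
    fall time > 150 ms AND peak amplitude > 125 µV.  Rise/fall are measured
    from the preceding/following crossing of 10% of the peak value.  The
    frontal trace is smoothed with a zero-phase ``smooth_hz`` low-pass
    before feature measurement (blinks live well below 15 Hz; smoothing
    keeps single noise samples from making or breaking a threshold).
    Detections on Fp1 and Fp2 that overlap are merged into one span.
    """
    raw = clean.raw
    missing = [c for c in channels if c not in raw.layout.retained]
    if missing:
        raise ValueError(f"frontal channels absent: {missing}")
    smooth_sos = None
    if smooth_hz and smooth_hz < raw.rate / 2.0:
        smooth_sos = signal.butter(4, smooth_hz, btype="lowpass", fs=raw.rate,
                                   output="sos")
    events: list[BlinkEvent] = []
    for ch in channels:
        x = raw.channel(ch)
        if smooth_sos is not None:
            x = signal.sosfiltfilt(smooth_sos, x)
        polarities = (1, -1) if both_polarities else (1,)
        for pol in polarities:
            events.extend(_blink_candidates(x, raw.rate, prescreen_uv, min_amp_uv,
                                            min_rise_ms, min_fall_ms, ch, pol))
    spans = merge_spans([Span(ev.onset, max(ev.offset, ev.onset + 1), "blink")
                         for ev in events])
    return clean.add_spans(spans), events


def clean_pipeline(raw: RawRecording, bp_low: float = 0.3, bp_high: float = 100.0,
                   threshold_uv: float = 200.0, pad_ms: float = 100.0,
                   lp_cutoff: float = 30.0,
                   blink_kwargs: dict | None = None) -> CleanRecording:
    """Full chain: bandpass -> average reference -> threshold -> blinks -> lowpass.

    Returns a CleanRecording whose ``raw`` is ERP-ready (30 Hz low-passed)
    and whose ``bad_spans`` union threshold and blink exclusions.
    """
    x = bandpass(raw, bp_low, bp_high)
    x = average_reference(x)
    clean = mark_threshold_artifacts(x, limit_uv=threshold_uv, pad_ms=pad_ms)
    clean, _ = detect_blinks(clean, **(blink_kwargs or {}))
    erp_ready = lowpass_for_erp(clean.raw, cutoff_hz=lp_cutoff)
    return CleanRecording(raw=erp_ready, bad_spans=clean.bad_spans)


def score_detector(detected: list[Span], truth: list[Span],
                   n_samples: int) -> tuple[float, float]:
    """(recall, precision) of detected spans against ground-truth spans.

    Recall: fraction of truth spans overlapped by any detection.
    Precision: fraction of detected spans overlapping any truth span.
    """
    if not truth:
        return (float("nan"), 0.0 if detected else float("nan"))
    hit = sum(any(t.overlaps(d.start, d.end) for d in detected) for t in truth)
    recall = hit / len(truth)
    if not detected:
        return (recall, float("nan"))
    good = sum(any(d.overlaps(t.start, t.end) for t in truth) for d in detected)
    return (recall, good / len(detected))
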