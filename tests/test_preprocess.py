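"""Filtering, re-referencing, and artifact/blink detection."""

import dataclasses

import numpy as np
import pytest

from emogo.core import ChannelLayout, Span, ms_to_sample
from emogo.preprocess import (CleanRecording, average_reference, bandpass,
                              clean_pipeline, detect_blinks, lowpass_for_erp,
                              mark_threshold_artifacts, score_detector)
from emogo.synth import gaussian_kernel, make_session, pink_noise

from conftest import make_raw


def sine(freq, rate=500.0, seconds=8.0, n_ch=28):
    t = np.arange(int(seconds * rate)) / rate
    return make_raw(np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)))


def amplitude(raw, guard=1500):
    """Peak amplitude away from the filter's edge-transient region."""
    return np.abs(raw.data[0, guard:-guard]).max()


class TestFilters:
    def test_bandpass_preserves_passband_tone(self):
        out = bandpass(sine(50.0))
        assert amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_bandpass_removes_slow_drift(self):
        out = bandpass(sine(0.05, seconds=60.0, n_ch=28))
        assert amplitude(out, guard=7500) < 0.1    # >= 90% attenuation

    def test_lowpass_preserves_10hz_and_removes_60hz(self):
        assert amplitude(lowpass_for_erp(sine(10.0))) == pytest.approx(1.0, rel=0.05)
        assert amplitude(lowpass_for_erp(sine(60.0))) < 0.1

    def test_lowpass_reduces_white_noise_variance(self, rng):
        raw = make_raw(rng.normal(size=(28, 4000)))
        assert lowpass_for_erp(raw).data.var() < raw.data.var()

    def test_zero_phase_peak_shift_below_2ms(self):
        t = np.arange(1500) * 2.0  # ms at 500 Hz
        bump = gaussian_kernel(t, 1500.0, 60.0)
        raw = make_raw(np.tile(bump, (28, 1)))
        for f in (bandpass, lowpass_for_erp):
            peak = np.argmax(f(raw).data[0])
            assert abs(t[peak] - 1500.0) <= 2.0

    def test_linearity(self, rng):
        x = make_raw(rng.normal(size=(28, 2000)))
        y = make_raw(rng.normal(size=(28, 2000)))
        combo = make_raw(2.0 * x.data + 3.0 * y.data)
        lhs = bandpass(combo).data
        rhs = 2.0 * bandpass(x).data + 3.0 * bandpass(y).data
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sine(10.0), 0.3, 300.0)

    def test_filters_are_logged(self):
        out = lowpass_for_erp(bandpass(sine(10.0)))
        assert [e["filter"] for e in out.filter_log] == ["bandpass", "lowpass"]


class TestAverageReference:
    def test_channel_mean_is_zero_everywhere(self, rng):
        out = average_reference(make_raw(rng.normal(size=(28, 1000))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_balanced_pair_unchanged(self):
        layout = ChannelLayout(names=("A", "B"), reference="A", ground="B",
                               excluded=frozenset())
        raw = make_raw(np.array([[5.0] * 10, [-5.0] * 10]), layout=layout)
        assert np.allclose(average_reference(raw).data, raw.data)

    def test_common_offset_removed(self):
        raw = make_raw(np.full((28, 100), 10.0))
        assert np.allclose(average_reference(raw).data, 0.0)

    def test_single_channel_rejected(self):
        layout = ChannelLayout(names=("A",), reference="A", ground="A",
                               excluded=frozenset())
        with pytest.raises(ValueError):
            average_reference(make_raw(np.zeros((1, 10)), layout=layout))


class TestThresholdArtifacts:
    def test_quiet_recording_has_no_spans(self):
        clean = mark_threshold_artifacts(make_raw(np.zeros((28, 1000))))
        assert clean.bad_spans == []

    def test_single_excursion_is_covered_and_padded(self):
        data = np.zeros((28, 1000))
        data[3, 400] = 250.0
        clean = mark_threshold_artifacts(make_raw(data), pad_ms=100.0)
        (span,) = clean.bad_spans
        assert span.start <= 400 < span.end
        assert span.end - span.start == pytest.approx(2 * 50 + 1, abs=1)

    def test_nearby_excursions_merge(self):
        data = np.zeros((28, 1000))
        data[0, 300] = 250.0
        data[5, 320] = -250.0
        clean = mark_threshold_artifacts(make_raw(data), pad_ms=100.0)
        assert len(clean.bad_spans) == 1


class TestBlinkDetector:
    @staticmethod
    def _pulse_session(rise_ms, fall_ms, amp, n=8000, peak_at=4000):
        data = np.zeros((28, n))
        layout = ChannelLayout()
        rise = ms_to_sample(rise_ms, 500.0)
        fall = ms_to_sample(fall_ms, 500.0)
        pulse = np.concatenate([np.linspace(0, amp, rise, endpoint=False),
                                np.linspace(amp, 0, fall)])
        for ch in ("Fp1", "Fp2"):
            data[layout.index(ch), peak_at - rise:peak_at + fall] += pulse
        return CleanRecording(raw=make_raw(data))

    def test_pulse_meeting_all_thresholds_is_detected(self):
        clean, events = detect_blinks(self._pulse_session(120, 180, 150.0))
        assert events
        assert any(s.kind == "blink" and s.start <= 4000 < s.end
                   for s in clean.bad_spans)

    @pytest.mark.parametrize("rise,fall,amp", [
        (80, 180, 150.0),    # rise too fast
        (120, 100, 150.0),   # fall too fast
        (120, 180, 100.0),   # too small
    ])
    def test_pulse_failing_any_threshold_is_ignored(self, rise, fall, amp):
        _, events = detect_blinks(self._pulse_session(rise, fall, amp))
        assert events == []

    def test_negative_polarity_detected_too(self):
        _, events = detect_blinks(self._pulse_session(120, 180, -150.0))
        assert events

    def test_missing_frontal_channel_is_an_error(self):
        layout = ChannelLayout(names=("A", "B"), reference="A", ground="B",
                               excluded=frozenset())
        clean = CleanRecording(raw=make_raw(np.zeros((2, 100)), layout=layout))
        with pytest.raises(ValueError, match="Fp1"):
            detect_blinks(clean)


@pytest.fixture(scope="module")
def long_session():
    import pandas as pd

    from emogo.synth import (ArtifactParams, BlinkParams, GeneratorParams,
                             NoiseParams, SubjectEffects)

    params = GeneratorParams(
        n_subjects=1, seed=0,
        blink=BlinkParams(rate_per_min=6.0),
        artifact=ArtifactParams(rate_per_min=4.0),
        noise=NoiseParams(pink_sd_uv=10.0, alpha_amp_uv=2.0),
        pad_ms=180_000.0,   # 6-minute blank session
    )
    empty = pd.DataFrame(columns=["trial_id", "block", "is_practice",
                                  "condition", "emotion", "identity"])
    effects = SubjectEffects(5.0, -3.0,
                             {e: 4.0 for e in ("angry", "neutral", "happy")},
                             {e: -2.0 for e in ("angry", "neutral", "happy")})
    rng = np.random.default_rng(777)
    raw, truth = make_session(empty, effects, params, rng)
    return raw, truth


class TestDetectorsOnSyntheticSession:
    """Score the detectors against the generator's ground truth."""

    def test_injected_blinks_exceed_detector_thresholds_by_construction(self, clean_generator):
        b = clean_generator.blink
        assert b.rise_ms[0] > 100.0 + 10.0
        assert b.fall_ms[0] > 150.0 + 10.0
        assert b.amp_uv[0] > 125.0 + 10.0

    def test_blink_recall_and_precision(self, long_session):
        raw, truth = long_session
        x = average_reference(bandpass(raw))
        clean, _ = detect_blinks(CleanRecording(raw=x))
        blink_truth = [s for s in truth if s.kind == "blink"]
        detected = [s for s in clean.bad_spans if s.kind == "blink"]
        recall, precision = score_detector(detected, blink_truth, raw.n_samples)
        assert recall == 1.0
        assert precision >= 0.95

    def test_gross_artifacts_fully_covered_with_little_overreach(self, long_session):
        raw, truth = long_session
        x = average_reference(bandpass(raw))
        clean = mark_threshold_artifacts(x)
        gross = [s for s in truth if s.kind == "gross"]
        assert gross
        covered = np.zeros(raw.n_samples, dtype=bool)
        for s in clean.bad_spans:
            covered[s.start:s.end] = True
        truthmask = np.zeros(raw.n_samples, dtype=bool)
        for s in truth:   # blinks may legitimately cross threshold too
            truthmask[s.start:s.end] = True
        for s in gross:
            assert covered[s.start:s.end].all()
        false_cover = (covered & ~truthmask).sum() / (~truthmask).sum()
        assert false_cover < 0.05


class TestPipelineOrder:
    def test_stage_order_is_logged(self, rng):
        raw = make_raw(rng.normal(size=(28, 4000)))
        clean = clean_pipeline(raw)
        names = [e["filter"] for e in clean.raw.filter_log]
        assert names == ["bandpass", "average_reference", "lowpass"]
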