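"""Epoching, baseline correction, amplitude scoring and difference scores."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from emogo.core import ChannelLayout, EventMarker, Span
from emogo.erp import (EpochSet, ErpSummary, average_erp, baseline_correct,
                       difference_scores, epoch, mean_amplitude, subject_qc,
                       summarize_erp)
from emogo.preprocess import CleanRecording
from emogo.synth import (gaussian_kernel, generate_cohort, effective_gain,
                         kernel_window_mean)

from conftest import make_raw


def _session_with_events(n_trials=6, rt=400.0, practice_flags=None, spacing=800):
    layout = ChannelLayout()
    n = 1000 + n_trials * spacing
    data = np.zeros((28, n))
    events, rows = [], []
    for i in range(n_trials):
        s = 500 + i * spacing
        practice = bool(practice_flags[i]) if practice_flags is not None else False
        events.append(EventMarker(sample=s, trial_id=i, condition="Go",
                                  emotion="happy", identity="m1",
                                  is_practice=practice))
        rows.append(dict(trial_id=i, block=1, is_practice=practice, condition="Go",
                         emotion="happy", identity="m1", go_duration_ms=550.0,
                         response_window_ms=550.0, responded=True, rt_ms=rt,
                         correct=True))
    raw = make_raw(data, events=events, layout=layout)
    return CleanRecording(raw=raw), pd.DataFrame(rows)


class TestEpoching:
    def test_clean_session_keeps_every_trial(self):
        clean, log = _session_with_events(6)
        eps = epoch(clean, log)
        assert eps.n_epochs == 6
        assert eps.data.shape == (6, 28, 550)   # 1100 ms at 500 Hz

    def test_artifact_span_drops_overlapping_trial(self):
        clean, log = _session_with_events(6)
        clean = clean.add_spans([Span(500 + 2 * 800 + 100, 500 + 2 * 800 + 150,
                                      "threshold")])
        eps = epoch(clean, log)
        assert eps.n_epochs == 5
        assert eps.drop_log.iloc[0].tolist() == [2, "threshold"]

    def test_anticipatory_response_dropped_with_reason(self):
        clean, log = _session_with_events(3)
        log.loc[1, "rt_ms"] = 150.0
        eps = epoch(clean, log)
        assert eps.n_epochs == 2
        assert eps.drop_log.iloc[0].tolist() == [1, "anticipatory"]

    def test_practice_trials_dropped(self):
        clean, log = _session_with_events(4, practice_flags=[True, True, False, False])
        eps = epoch(clean, log)
        assert eps.n_epochs == 2
        assert set(eps.drop_log["reason"]) == {"practice"}

    def test_zero_surviving_epochs_is_explicit_not_an_error(self):
        clean, log = _session_with_events(3, rt=150.0)
        eps = epoch(clean, log)
        assert eps.n_epochs == 0
        assert len(eps.drop_log) == 3


class TestBaseline:
    def _eps(self, data):
        n_ep, n_ch, n_s = data.shape
        times = (np.arange(n_s) - 50) * 2.0
        meta = pd.DataFrame(dict(trial_id=range(n_ep), condition="Go",
                                 emotion="happy", correct=True, rt_ms=400.0))
        return EpochSet(data=data, times_ms=times,
                        channels=ChannelLayout().retained[:n_ch] if n_ch == 28
                        else tuple(f"c{i}" for i in range(n_ch)),
                        meta=meta, drop_log=pd.DataFrame(columns=["trial_id", "reason"]))

    def test_constant_epoch_becomes_zero(self):
        eps = baseline_correct(self._eps(np.full((1, 28, 550), 7.0)))
        assert np.allclose(eps.data, 0.0)

    def test_offset_shifts_post_stimulus_bump(self):
        data = np.full((1, 28, 550), 2.0)
        data[:, :, 300:330] += 5.0
        eps = baseline_correct(self._eps(data))
        assert np.allclose(eps.data[:, :, :50], 0.0)
        assert np.allclose(eps.data[:, :, 300:330], 5.0)

    def test_random_epochs_have_zero_baseline_mean(self, rng):
        eps = baseline_correct(self._eps(rng.normal(size=(10, 28, 550))))
        base = eps.data[:, :, :50].mean(axis=2)
        assert np.abs(base).max() < 1e-9


class TestAveraging:
    def _eps_with_meta(self, data, conditions, emotions, correct=None):
        n_ep = data.shape[0]
        meta = pd.DataFrame(dict(trial_id=range(n_ep), condition=conditions,
                                 emotion=emotions,
                                 correct=correct if correct is not None else [True] * n_ep,
                                 rt_ms=400.0))
        times = (np.arange(data.shape[2]) - 50) * 2.0
        return EpochSet(data=data, times_ms=times, channels=ChannelLayout().retained,
                        meta=meta, drop_log=pd.DataFrame(columns=["trial_id", "reason"]),
                        baseline_corrected=True)

    def test_identical_epochs_average_to_themselves(self, rng):
        ep0 = rng.normal(size=(28, 550))
        eps = self._eps_with_meta(np.tile(ep0, (10, 1, 1)), ["NoGo"] * 10, ["happy"] * 10)
        wave, n = average_erp(eps, "NoGo", "happy")
        assert n == 10
        assert np.allclose(wave, ep0)

    def test_noise_shrinks_as_root_n(self, rng):
        signal = gaussian_kernel((np.arange(550) - 50) * 2.0, 540.0, 60.0) * 5.0
        rms = {}
        for n in (4, 16, 64):
            data = signal[None, None, :] + rng.normal(size=(n, 28, 550))
            eps = self._eps_with_meta(data, ["Go"] * n, ["happy"] * n)
            wave, _ = average_erp(eps, "Go", "happy")
            rms[n] = np.sqrt(np.mean((wave - signal[None, :]) ** 2))
        assert rms[16] == pytest.approx(rms[4] / 2, rel=0.25)
        assert rms[64] == pytest.approx(rms[16] / 2, rel=0.25)

    def test_selection_counts_only_matching_correct_epochs(self, rng):
        n = 16
        correct = [True] * 14 + [False] * 2
        eps = self._eps_with_meta(rng.normal(size=(n, 28, 550)),
                                  ["NoGo"] * n, ["happy"] * n, correct)
        _, n_valid = average_erp(eps, "NoGo", "happy", correct_only=True)
        assert n_valid == 14

    def test_empty_cell_flagged(self, rng):
        eps = self._eps_with_meta(rng.normal(size=(2, 28, 550)), ["Go"] * 2, ["happy"] * 2)
        wave, n = average_erp(eps, "NoGo", "angry")
        assert wave is None and n == 0

    def test_averaging_is_linear_in_a_constant_shift(self, rng):
        data = rng.normal(size=(8, 28, 550))
        eps = self._eps_with_meta(data, ["Go"] * 8, ["happy"] * 8)
        eps2 = self._eps_with_meta(data + 3.0, ["Go"] * 8, ["happy"] * 8)
        w1, _ = average_erp(eps, "Go", "happy")
        w2, _ = average_erp(eps2, "Go", "happy")
        assert np.allclose(w2, w1 + 3.0, atol=1e-9)


class TestMeanAmplitude:
    times = (np.arange(550) - 50) * 2.0
    channels = ChannelLayout().retained

    def test_constant_waveform(self):
        wave = np.full((28, 550), 5.0)
        assert mean_amplitude(wave, self.times, (480, 600), self.channels) == 5.0

    def test_gaussian_window_average_matches_fine_grid_oracle(self):
        fz = self.channels.index("Fz")
        wave = np.zeros((28, 550))
        wave[fz] = 7.0 * gaussian_kernel(self.times, 540.0, 60.0)
        got = mean_amplitude(wave, self.times, (480.0, 600.0), self.channels)
        # oracle on the same sample grid (inclusive endpoints)
        grid = self.times[(self.times >= 480) & (self.times <= 600)]
        expect = 7.0 * gaussian_kernel(grid, 540.0, 60.0).mean()
        assert got == pytest.approx(expect, abs=1e-12)
        # and within 1% of the continuous-time average
        assert got == pytest.approx(kernel_window_mean(7.0, 540.0, 60.0, (480.0, 600.0)),
                                    rel=0.01)

    def test_n2_window_sees_little_of_the_p3_kernel(self):
        fz = self.channels.index("Fz")
        wave = np.zeros((28, 550))
        wave[fz] = 7.0 * gaussian_kernel(self.times, 540.0, 60.0)
        p3 = mean_amplitude(wave, self.times, (480.0, 600.0), self.channels)
        n2 = mean_amplitude(wave, self.times, (300.0, 400.0), self.channels)
        assert abs(n2) < 0.1 * abs(p3)

    def test_absent_channel_is_an_error(self):
        with pytest.raises(KeyError):
            mean_amplitude(np.zeros((28, 550)), self.times, (480, 600),
                           self.channels, channel="Xz")


class TestDifferenceScores:
    @staticmethod
    def _summary(p3):
        rows = []
        for cond in ("Go", "NoGo"):
            for emo in ("angry", "neutral", "happy"):
                rows.append(dict(condition=cond, emotion=emo, n2_uv=0.0,
                                 p3_uv=p3[(cond, emo)], n_valid=10))
        return ErpSummary(cells=pd.DataFrame(rows))

    def test_equal_conditions_give_zero_differences(self):
        p3 = {(c, e): 3.0 for c in ("Go", "NoGo") for e in ("angry", "neutral", "happy")}
        out = difference_scores(self._summary(p3))
        assert np.allclose(out.diffs["p3d_uv"], 0.0)

    def test_simple_subtraction(self):
        p3 = {(c, e): 2.0 for c in ("Go", "NoGo") for e in ("angry", "neutral", "happy")}
        p3[("NoGo", "happy")] = 6.0
        out = difference_scores(self._summary(p3))
        assert out.diffs.set_index("emotion").loc["happy", "p3d_uv"] == pytest.approx(4.0)

    def test_emotion_contrast_identity(self, rng):
        p3 = {(c, e): float(rng.normal()) for c in ("Go", "NoGo")
              for e in ("angry", "neutral", "happy")}
        out = difference_scores(self._summary(p3))
        d = out.diffs.set_index("emotion")["p3d_uv"]
        c = out.contrasts.set_index(["emotion", "component"])
        for emo in ("angry", "happy"):
            # NoGo-Go of (emotion - neutral) == P3d(emotion) - P3d(neutral)
            assert c.loc[(emo, "p3"), "nogo_minus_go"] == pytest.approx(
                d[emo] - d["neutral"], abs=1e-9)

    def test_missing_cell_propagates_nan(self):
        p3 = {(c, e): 1.0 for c in ("Go", "NoGo") for e in ("angry", "neutral", "happy")}
        summary = self._summary(p3)
        summary.cells.loc[(summary.cells.condition == "NoGo")
                          & (summary.cells.emotion == "happy"), "p3_uv"] = np.nan
        out = difference_scores(summary)
        assert np.isnan(out.diffs.set_index("emotion").loc["happy", "p3d_uv"])


class TestSubjectQc:
    @staticmethod
    def _summary(n_valid):
        rows = [dict(condition=c, emotion=e, n2_uv=0.0, p3_uv=0.0, n_valid=n_valid)
                for c in ("Go", "NoGo") for e in ("angry", "neutral", "happy")]
        return ErpSummary(cells=pd.DataFrame(rows))

    def test_low_accuracy_excludes_from_everything(self):
        qc = subject_qc(self._summary(10), overall_accuracy=45.0)
        assert not qc.included_behavior and not qc.included_erp
        assert "accuracy" in qc.reasons[0]

    def test_good_subject_included(self):
        qc = subject_qc(self._summary(10), overall_accuracy=80.0)
        assert qc.included_behavior and qc.included_erp

    def test_sparse_cell_excludes_from_erp_only(self):
        summary = self._summary(10)
        summary.cells.loc[5, "n_valid"] = 2
        qc = subject_qc(summary, overall_accuracy=80.0)
        assert qc.included_behavior and not qc.included_erp
        assert "valid trials" in qc.reasons[0]


class TestKernelRecovery:
    """Noiseless end-to-end: extracted window means match the closed form."""

    def test_noiseless_session_recovers_kernel_window_means(self, clean_generator):
        params = dataclasses.replace(
            clean_generator,
            noise=dataclasses.replace(clean_generator.noise, pink_sd_uv=0.0,
                                      alpha_amp_uv=0.0),
            erp=dataclasses.replace(clean_generator.erp, trial_amp_sd=0.0,
                                    p3d_subject_sd=0.0, n2d_subject_sd=0.0,
                                    go_subject_sd=0.0),
            coupling_p3d_happy=0.0,
        )
        (sub,) = generate_cohort(params)
        from emogo.erp import epoch as do_epoch
        from emogo.preprocess import CleanRecording, average_reference

        # no filtering: direct epoching isolates the kernel arithmetic
        clean = CleanRecording(raw=average_reference(sub.raw))
        eps = baseline_correct(do_epoch(clean, sub.trial_log))
        summary = difference_scores(summarize_erp(eps))
        gain = effective_gain("Fz")
        erp = params.erp
        for emo in ("angry", "neutral", "happy"):
            got = summary.diffs.set_index("emotion").loc[emo, "p3d_uv"]
            expect = gain * kernel_window_mean(erp.p3_nogo_increment_uv,
                                               erp.p3_center_ms, erp.p3_width_ms,
                                               (480.0, 600.0))
            assert got == pytest.approx(expect, abs=0.01)
            got_n2 = summary.diffs.set_index("emotion").loc[emo, "n2d_uv"]
            expect_n2 = gain * kernel_window_mean(erp.n2_nogo_increment_uv,
                                                  erp.n2_center_ms, erp.n2_width_ms,
                                                  (300.0, 400.0))
            # N2 window also catches the P3 kernel's left tail
            expect_n2 += gain * kernel_window_mean(erp.p3_nogo_increment_uv,
                                                   erp.p3_center_ms, erp.p3_width_ms,
                                                   (300.0, 400.0))
            assert got_n2 == pytest.approx(expect_n2, abs=0.05)
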