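"""Synthetic study generator.

Produces complete cohorts with the statistical structure the analysis
assumes, so every downstream stage can be validated against known ground
truth:

* latent traits (disordered eating, anxiety, depression) drawn from a
  configurable correlation matrix;
* questionnaire item responses from a single-factor graded model (loading
  0.9, equal-probability thresholds) so observed-score correlations track
  the latent ones with little attenuation;
* adaptive Go/NoGo behavior (hit/commission probabilities, shifted
  log-normal RTs, anticipatory responses) run through the real staircase;
* continuous 32-channel, 500 Hz EEG: pink-noise background + alpha,
  stimulus-locked Gaussian N2/P3 kernels (negative ~350 ms / positive
  ~540 ms, larger on NoGo) with a frontocentral topography peaking at Fz,
  triangular blink pulses at Fp1/Fp2 and gross >200 µV excursions, each
  with ground-truth span annotations;
* a subject-level coupling between the disordered-eating latent and the
  NoGo-minus-Go P3 amplitude on happy trials, the effect the inference
  layer is built to recover.

Acquisition is modelled as Cz-referenced: each channel carries
``(w_ch - w_Cz) * s(t)`` for a component with scalp weight ``w`` and time
course ``s``; the average re-reference applied downstream then yields
``(w_ch - mean(w)) * s(t)``, captured by :func:`effective_gain`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from emogo.core import (ACTICAP32, EMOTIONS, ChannelLayout, EventMarker,
                        RawRecording, Span, ms_to_sample)
from emogo.task import (AdaptState, TaskSpec, build_trial_list, response_window,
                        trial_outcome, update_adaptation)
from emogo.behavior import build_morph_inventory
from emogo.questionnaires import (CHEAT_OPTIONS, RCADS_OPTIONS, N_CHEAT_ITEMS,
                                  RCADS_ANXIETY_ITEMS, RCADS_DEPRESSION_ITEMS)

#: Relative scalp weight of the N2/P3 generator, peaking at Fz.
FRONTOCENTRAL_TOPOGRAPHY: dict[str, float] = {
    "Fp1": 0.45, "Fp2": 0.45, "F7": 0.45, "F3": 0.75, "Fz": 1.00, "F4": 0.75,
    "F8": 0.45, "FT9": 0.20, "FC5": 0.50, "FC1": 0.85, "FC2": 0.85, "FC6": 0.50,
    "FT10": 0.20, "T7": 0.25, "C3": 0.60, "Cz": 0.80, "C4": 0.60, "T8": 0.25,
    "TP9": 0.10, "CP5": 0.30, "CP1": 0.45, "CP2": 0.45, "CP6": 0.30, "TP10": 0.10,
    "P7": 0.15, "P3": 0.30, "Pz": 0.40, "P4": 0.30, "P8": 0.15,
    "O1": 0.10, "Oz": 0.10, "O2": 0.10,
}

#: Blink spatial spread (dominant at the frontal poles).
BLINK_TOPOGRAPHY: dict[str, float] = {
    "Fp1": 1.00, "Fp2": 0.95, "F7": 0.30, "F8": 0.30,
    "F3": 0.20, "F4": 0.20, "Fz": 0.20,
}


@dataclass(frozen=True)
class ErpKernelParams:
    """Gaussian-bump ERP component model (amplitudes in µV at the Fz weight).

    The NoGo increments carry the inhibition effect; per-subject increment
    variability (``p3d_subject_sd``) is the between-subject signal that the
    trait coupling modulates on happy trials.
    """

    n2_center_ms: float = 350.0
    n2_width_ms: float = 40.0
    n2_amp_uv: float = -3.0
    n2_nogo_increment_uv: float = -2.0
    n2d_subject_sd: float = 1.5
    p3_center_ms: float = 540.0
    p3_width_ms: float = 60.0
    p3_amp_uv: float = 5.0
    p3_nogo_increment_uv: float = 4.0
    p3d_subject_sd: float = 6.0
    go_subject_sd: float = 1.5
    trial_amp_sd: float = 1.0
    emotion_offsets_uv: tuple[tuple[str, float, float], ...] = (
        ("angry", 0.0, 0.0), ("neutral", 0.0, 0.0), ("happy", 0.0, 0.0),
    )  # (emotion, n2 offset, p3 offset)

    def offsets(self, emotion: str) -> tuple[float, float]:
        for emo, n2, p3 in self.emotion_offsets_uv:
            if emo == emotion:
                return n2, p3
        return 0.0, 0.0


@dataclass(frozen=True)
class NoiseParams:
    pink_sd_uv: float = 10.0
    alpha_amp_uv: float = 2.0
    alpha_hz: float = 10.0


@dataclass(frozen=True)
class BlinkParams:
    """Triangular blink pulses at Fp1/Fp2.

    Ranges are chosen so every injected blink clears the detector's
    rise/fall/amplitude thresholds with margin even after the band-pass
    (whose high-pass limb saps pulse amplitude and undershoots the tail)
    and average re-referencing (~0.9 frontal scaling) under background
    noise.  Large blinks may also cross the ±200 µV gross threshold, as
    real ones do; both exclusions apply.
    """

    rate_per_min: float = 12.0
    rise_ms: tuple[float, float] = (140.0, 200.0)
    fall_ms: tuple[float, float] = (220.0, 320.0)
    amp_uv: tuple[float, float] = (190.0, 240.0)
    min_separation_ms: float = 700.0


@dataclass(frozen=True)
class ArtifactParams:
    """Gross half-sine excursions on a random channel.

    The amplitude floor keeps the pulse's sub-threshold skirt (the edge
    region where |x| has not yet reached ±200 µV) shorter than the
    100 ms span padding, so injected artifacts are fully covered by the
    padded threshold spans by construction.
    """

    rate_per_min: float = 1.0
    amp_uv: tuple[float, float] = (300.0, 450.0)
    duration_ms: tuple[float, float] = (100.0, 300.0)


@dataclass(frozen=True)
class BehaviorParams:
    """Trial-response model (defaults emulate preadolescent performance).

    Responses are collected over the deliberate band
    ``[rt_min_ms, rt_max_ms]`` (children keep responding after stimulus
    offset); RTs come from a shifted log-normal truncated to that band,
    and anticipatory (<200 ms) responses are injected separately.
    """

    go_hit_p: float = 0.75
    nogo_commission_p: float = 0.29
    anticipatory_p: float = 0.03
    rt_shift_ms: float = 150.0
    rt_meanlog: float = 5.64   # log ms of the shifted component (median ~281 ms)
    rt_sdlog: float = 0.35
    nogo_rt_scale: float = 0.85
    rt_min_ms: float = 200.0
    rt_max_ms: float = 1200.0


@dataclass(frozen=True)
class RecognitionParams:
    """Card-sorting response model for the morph task."""

    base_accuracy: tuple[tuple[str, float], ...] = (
        ("happy", 0.67), ("angry", 0.76), ("sad", 0.68),
    )
    intensity_slope: float = 0.5      # p(correct) gain per unit intensity above mid
    neutral_accuracy: float = 0.85
    to_neutral_p: float = 0.7         # errors land in the neutral box with this prob
    coupling_happy: float = 0.0       # shift in p(correct|happy) per DE latent SD

    def base(self, emotion: str) -> float:
        for emo, p in self.base_accuracy:
            if emo == emotion:
                return p
        return 0.7


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic study, with study-condition defaults."""

    n_subjects: int = 53
    seed: int = 0
    #: latent order (disordered eating, anxiety, depression)
    trait_corr: tuple[tuple[float, ...], ...] = (
        (1.00, 0.64, 0.43),
        (0.64, 1.00, 0.60),
        (0.43, 0.60, 1.00),
    )
    item_loading: float = 0.9
    task: TaskSpec = field(default_factory=TaskSpec)
    erp: ErpKernelParams = field(default_factory=ErpKernelParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    blink: BlinkParams = field(default_factory=BlinkParams)
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    recognition: RecognitionParams = field(default_factory=RecognitionParams)
    #: µV of P3d(happy) per SD of the disordered-eating latent; the default
    #: calibrates the generator-level correlation to ~0.32 at the default
    #: p3d_subject_sd of 6 µV (see coupling_for_target_r); set 0 for null
    #: cohorts
    coupling_p3d_happy: float = 2.027
    rate: float = 500.0
    onset_interval_ms: float = 1600.0
    onset_jitter_ms: float = 150.0
    pad_ms: float = 2000.0
    make_eeg: bool = True
    male_fraction: float = 0.566
    age_range: tuple[float, float] = (10.0, 11.83)
    #: per-subject-index behavior overrides (e.g. to force a QC failure)
    behavior_overrides: tuple[tuple[int, BehaviorParams], ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.trait_corr, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("trait_corr must be a symmetric 3x3 matrix with unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("trait_corr must be positive definite")


def coupling_for_target_r(rho: float, p3d_subject_sd: float) -> float:
    """Coupling slope giving generator-level corr(DE latent, P3d happy) = rho."""
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    return rho / np.sqrt(1.0 - rho ** 2) * p3d_subject_sd


def effective_gain(channel: str, layout: ChannelLayout | None = None,
                   topography: dict[str, float] = FRONTOCENTRAL_TOPOGRAPHY) -> float:
    """Component gain at ``channel`` after Cz-referencing + average reference.

    The Cz-referenced signal at channel c is ``(w_c - w_Cz) s(t)``; average
    re-referencing over the retained channels turns it into
    ``(w_c - mean_retained(w)) s(t)``.
    """
    layout = layout or ChannelLayout()
    w = np.array([topography[c] for c in layout.retained])
    return float(topography[channel] - w.mean())


def gaussian_kernel(t_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / width_ms) ** 2)


def kernel_window_mean(amp_uv: float, center_ms: float, width_ms: float,
                       window_ms: tuple[float, float], n_grid: int = 200_001) -> float:
    """Fine-grid average of a Gaussian bump over a latency window (µV).

    Oracle for the extraction path: a noiseless averaged epoch's mean
    amplitude over the window must match this closed-form value.
    """
    t = np.linspace(window_ms[0], window_ms[1], n_grid)
    return float(amp_uv * gaussian_kernel(t, center_ms, width_ms).mean())


# ---------------------------------------------------------------------------
# latent traits and questionnaire items


def generate_latents(n: int, trait_corr, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) latent z-scores with the requested correlation structure."""
    c = np.asarray(trait_corr, dtype=float)
    if np.linalg.eigvalsh(c).min() <= 0:
        raise ValueError("trait correlation matrix must be positive definite")
    chol = np.linalg.cholesky(c)
    return rng.standard_normal((n, 3)) @ chol.T


def graded_items(latent: np.ndarray, n_items: int, n_categories: int,
                 loading: float, rng: np.random.Generator) -> np.ndarray:
    """Discretized single-factor item responses, codes 0..n_categories-1.

    Continuous item value = loading * latent + sqrt(1 - loading^2) * noise,
    cut at equal-probability standard-normal thresholds.
    """
    n = len(latent)
    y = loading * latent[:, None] + np.sqrt(1 - loading ** 2) * rng.standard_normal((n, n_items))
    cuts = sps.norm.ppf(np.arange(1, n_categories) / n_categories)
    return np.digitize(y, cuts)


# ---------------------------------------------------------------------------
# behavior


def _truncated_lognorm_rt(rng: np.random.Generator, bp: BehaviorParams,
                          n: int, scale: float = 1.0) -> np.ndarray:
    """n RTs in [rt_min_ms, rt_max_ms] from the shifted log-normal model."""
    meanlog = bp.rt_meanlog + np.log(scale)
    a = max(1.0, bp.rt_min_ms - bp.rt_shift_ms)
    b = max(a + 1.0, bp.rt_max_ms - bp.rt_shift_ms)
    za = (np.log(a) - meanlog) / bp.rt_sdlog
    zb = (np.log(b) - meanlog) / bp.rt_sdlog
    u = rng.uniform(sps.norm.cdf(za), sps.norm.cdf(zb), size=n)
    return bp.rt_shift_ms + np.exp(meanlog + bp.rt_sdlog * sps.norm.ppf(u))


def simulate_behavior(trial_log: pd.DataFrame, spec: TaskSpec, bp: BehaviorParams,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Run the adaptive staircase over a trial skeleton, drawing responses.

    Go trials are responded to with probability ``go_hit_p``; NoGo trials
    draw commissions with ``nogo_commission_p``; with probability
    ``anticipatory_p`` a trial instead receives an anticipatory (<200 ms)
    response.  RTs come from the truncated shifted log-normal.
    Correctness is raw (response on Go; no response on NoGo); the
    deliberate-response scoring rule is applied by the behavior module,
    not here.  The staircase updates on every non-practice trial (practice
    too if ``spec.adapt_during_practice``).
    """
    df = trial_log.copy()
    n = len(df)
    cond = df["condition"].to_numpy()
    practice = df["is_practice"].to_numpy(dtype=bool)
    is_go = cond == "Go"

    u_ant = rng.uniform(size=n)
    u_resp = rng.uniform(size=n)
    rt_ant = rng.uniform(100.0, 199.0, size=n)
    rt_go = _truncated_lognorm_rt(rng, bp, n)
    rt_nogo = _truncated_lognorm_rt(rng, bp, n, scale=bp.nogo_rt_scale)

    anticipatory = u_ant < bp.anticipatory_p
    responded = np.where(anticipatory, True,
                         u_resp < np.where(is_go, bp.go_hit_p, bp.nogo_commission_p))
    rt = np.where(anticipatory, rt_ant, np.where(is_go, rt_go, rt_nogo))
    rt = np.where(responded, rt, np.nan)
    correct = np.where(is_go, responded, ~responded)

    durations = np.empty(n)
    windows = np.empty(n)
    state = AdaptState(spec.initial_go_duration_ms)
    for i in range(n):
        durations[i] = state.current_duration_ms
        windows[i] = response_window(cond[i], durations[i], spec)
        if not practice[i] or spec.adapt_during_practice:
            state = update_adaptation(state, trial_outcome(cond[i], bool(correct[i])), spec)

    df["go_duration_ms"] = durations
    df["response_window_ms"] = windows
    df["responded"] = pd.array(responded, dtype="boolean")
    df["rt_ms"] = rt
    df["correct"] = pd.array(correct, dtype="boolean")
    return df


# ---------------------------------------------------------------------------
# EEG session


# 3-pole/3-zero pinking filter (Kellet): white noise in, ~1/f power out.
_PINK_B = (0.049922035, -0.095993537, 0.050612699, -0.004408786)
_PINK_A = (1.0, -2.494956002, 2.017265875, -0.522189400)


def pink_noise(n_channels: int, n_samples: int, sd_uv: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f-power background noise, independent per channel, std = sd_uv.

    White Gaussian noise shaped by the standard 3-pole/3-zero pinking
    filter; a 1-second warm-up segment absorbs the filter transient.
    """
    from scipy.signal import lfilter

    warm = 500
    white = rng.standard_normal((n_channels, n_samples + warm))
    x = lfilter(_PINK_B, _PINK_A, white, axis=1)[:, warm:]
    x /= x.std(axis=1, keepdims=True)
    return sd_uv * np.ascontiguousarray(x)


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject ERP amplitude parameters (ground truth for recovery tests)."""

    p3_go_uv: float
    n2_go_uv: float
    p3_nogo_increment_uv: dict[str, float]   # emotion -> true P3d amplitude
    n2_nogo_increment_uv: dict[str, float]


def draw_subject_effects(de_latent: float, erp: ErpKernelParams,
                         coupling_p3d_happy: float,
                         rng: np.random.Generator) -> SubjectEffects:
    p3_inc, n2_inc = {}, {}
    for emo in EMOTIONS:
        p3 = erp.p3_nogo_increment_uv + erp.p3d_subject_sd * rng.standard_normal()
        if emo == "happy":
            p3 += coupling_p3d_happy * de_latent
        p3_inc[emo] = float(p3)
        n2_inc[emo] = float(erp.n2_nogo_increment_uv
                            + erp.n2d_subject_sd * rng.standard_normal())
    return SubjectEffects(
        p3_go_uv=float(erp.p3_amp_uv + erp.go_subject_sd * rng.standard_normal()),
        n2_go_uv=float(erp.n2_amp_uv + 0.5 * erp.go_subject_sd * rng.standard_normal()),
        p3_nogo_increment_uv=p3_inc, n2_nogo_increment_uv=n2_inc,
    )


def _poisson_times(rate_per_min: float, n_samples: int, rate: float,
                   rng: np.random.Generator, margin: int) -> np.ndarray:
    dur_min = n_samples / rate / 60.0
    k = rng.poisson(rate_per_min * dur_min)
    if k == 0:
        return np.empty(0, dtype=int)
    lo, hi = margin, max(margin + 1, n_samples - margin)
    return np.sort(rng.integers(lo, hi, size=k))


def make_session(trial_log: pd.DataFrame, effects: SubjectEffects,
                 params: GeneratorParams, rng: np.random.Generator,
                 ) -> tuple[RawRecording, list[Span]]:
    """Continuous EEG for one session, with ground-truth annotations.

    Raises if the inter-onset interval cannot contain a full epoch.
    """
    layout = ChannelLayout()
    retained = layout.retained
    rate = params.rate
    erp = params.erp
    n_trials = len(trial_log)
    if params.onset_interval_ms < 1200.0:
        raise ValueError("trial spacing shorter than the epoch span (-100..1000 ms)")

    jitter = rng.uniform(0, params.onset_jitter_ms, size=n_trials)
    onsets_ms = params.pad_ms + np.arange(n_trials) * params.onset_interval_ms + jitter
    onsets = np.array([ms_to_sample(t, rate) for t in onsets_ms])
    n_samples = onsets[-1] + ms_to_sample(params.onset_interval_ms + params.pad_ms, rate) \
        if n_trials else ms_to_sample(2 * params.pad_ms, rate)

    n_ch = len(retained)
    if params.noise.pink_sd_uv > 0:
        data = pink_noise(n_ch, n_samples, params.noise.pink_sd_uv, rng)
    else:
        data = np.zeros((n_ch, n_samples))
    if params.noise.alpha_amp_uv > 0:
        t = np.arange(n_samples) / rate
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        data += params.noise.alpha_amp_uv * np.sin(
            2 * np.pi * params.noise.alpha_hz * t[None, :] + phases[:, None])

    # stimulus-locked components, Cz-referenced topography
    w = np.array([FRONTOCENTRAL_TOPOGRAPHY[c] for c in retained])
    w_ref = w - FRONTOCENTRAL_TOPOGRAPHY[layout.reference]
    k_len = ms_to_sample(1000.0, rate)
    t_ms = np.arange(k_len) * 1000.0 / rate
    g_n2 = gaussian_kernel(t_ms, erp.n2_center_ms, erp.n2_width_ms)
    g_p3 = gaussian_kernel(t_ms, erp.p3_center_ms, erp.p3_width_ms)

    events: list[EventMarker] = []
    for (row, onset) in zip(trial_log.itertuples(), onsets):
        n2_off, p3_off = erp.offsets(row.emotion)
        n2_amp = effects.n2_go_uv + n2_off
        p3_amp = effects.p3_go_uv + p3_off
        if row.condition == "NoGo":
            n2_amp += effects.n2_nogo_increment_uv[row.emotion]
            p3_amp += effects.p3_nogo_increment_uv[row.emotion]
        if erp.trial_amp_sd > 0:
            n2_amp += erp.trial_amp_sd * rng.standard_normal()
            p3_amp += erp.trial_amp_sd * rng.standard_normal()
        sig = n2_amp * g_n2 + p3_amp * g_p3
        data[:, onset:onset + k_len] += np.outer(w_ref, sig[: max(0, min(k_len, n_samples - onset))])
        events.append(EventMarker(sample=int(onset), trial_id=int(row.trial_id),
                                  condition=row.condition, emotion=row.emotion,
                                  identity=row.identity,
                                  is_practice=bool(row.is_practice)))

    truth: list[Span] = []
    # blinks: triangular pulses at the frontal poles (physiologically spaced)
    margin = ms_to_sample(600.0, rate)
    blink_peaks = _poisson_times(params.blink.rate_per_min, n_samples, rate, rng, margin)
    min_gap = ms_to_sample(params.blink.min_separation_ms, rate)
    kept_peaks = []
    for p in blink_peaks:
        if not kept_peaks or p - kept_peaks[-1] >= min_gap:
            kept_peaks.append(p)
    for peak in kept_peaks:
        rise = ms_to_sample(rng.uniform(*params.blink.rise_ms), rate)
        fall = ms_to_sample(rng.uniform(*params.blink.fall_ms), rate)
        amp = rng.uniform(*params.blink.amp_uv)
        start, end = peak - rise, peak + fall
        pulse = np.concatenate([np.linspace(0, amp, rise, endpoint=False),
                                np.linspace(amp, 0, fall)])
        for ch, bw in BLINK_TOPOGRAPHY.items():
            if ch in retained:
                data[layout.index(ch), start:end] += bw * pulse[: end - start]
        truth.append(Span(int(start), int(end), "blink"))

    # gross artifacts: half-sine excursions on one random channel
    for center in _poisson_times(params.artifact.rate_per_min, n_samples, rate, rng, margin):
        dur = ms_to_sample(rng.uniform(*params.artifact.duration_ms), rate)
        amp = rng.uniform(*params.artifact.amp_uv) * rng.choice([-1.0, 1.0])
        ch = int(rng.integers(n_ch))
        start, end = center - dur // 2, center - dur // 2 + dur
        data[ch, start:end] += amp * np.sin(np.linspace(0, np.pi, dur))
        truth.append(Span(int(start), int(end), "gross"))

    raw = RawRecording(data=data, rate=rate, layout=layout, events=events,
                       annotations=list(truth))
    return raw, truth


# ---------------------------------------------------------------------------
# recognition records


def simulate_recognition(de_latent: float, params: RecognitionParams,
                         rng: np.random.Generator,
                         inventory: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sorting choices for the full card inventory."""
    inv = build_morph_inventory() if inventory is None else inventory
    emotions = [e for e in inv["true_label"].unique() if e != "neutral"]
    chosen = []
    for row in inv.itertuples():
        if row.true_label == "neutral":
            p = params.neutral_accuracy
        else:
            p = params.base(row.true_label) + params.intensity_slope * (row.intensity - 0.55)
            if row.true_label == "happy":
                p += params.coupling_happy * de_latent
            p = float(np.clip(p, 0.02, 0.98))
        if rng.uniform() < p:
            chosen.append(row.true_label)
        elif row.true_label != "neutral" and rng.uniform() < params.to_neutral_p:
            chosen.append("neutral")
        else:
            others = [e for e in emotions + ["neutral"] if e != row.true_label]
            chosen.append(others[int(rng.integers(len(others)))])
    return pd.DataFrame({"card_id": inv["card_id"], "chosen_label": chosen})


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SyntheticSubject:
    """One simulated child: traits, responses, and (optionally) EEG."""

    subject_id: str
    age: float
    gender: str
    latents: dict[str, float]
    cheat_items: np.ndarray      # codes 0..5
    rcads_items: np.ndarray      # codes 0..3
    trial_log: pd.DataFrame
    effects: SubjectEffects
    raw: RawRecording | None = None
    ground_truth: list[Span] = field(default_factory=list)
    recognition: pd.DataFrame | None = None

    @property
    def true_p3d(self) -> dict[str, float]:
        return self.effects.p3_nogo_increment_uv


def generate_cohort(params: GeneratorParams) -> list[SyntheticSubject]:
    """Deterministic synthetic cohort for a fixed ``params.seed``.

    Materializes the whole cohort; for large-n EEG cohorts prefer
    :func:`iter_cohort`, which yields one subject at a time (a session is
    tens of MB).
    """
    return list(iter_cohort(params))


def iter_cohort(params: GeneratorParams):
    """Yield subjects one at a time (memory-bounded generation).

    Per-subject randomness comes from spawned seed sequences, so cohorts
    are extensible without reshuffling earlier subjects.
    """
    if params.n_subjects == 0:
        return
    root = np.random.SeedSequence(params.seed)
    subject_ss = root.spawn(params.n_subjects)
    chol = np.linalg.cholesky(np.asarray(params.trait_corr, dtype=float))
    overrides = dict(params.behavior_overrides)

    for i in range(params.n_subjects):
        rng = np.random.default_rng(subject_ss[i])
        latent = chol @ rng.standard_normal(3)   # (de, anxiety, depression)
        cheat = graded_items(latent[:1], N_CHEAT_ITEMS, len(CHEAT_OPTIONS),
                             params.item_loading, rng)[0]
        anx = graded_items(latent[1:2], len(RCADS_ANXIETY_ITEMS), len(RCADS_OPTIONS),
                           params.item_loading, rng)[0]
        dep = graded_items(latent[2:3], len(RCADS_DEPRESSION_ITEMS), len(RCADS_OPTIONS),
                           params.item_loading, rng)[0]
        age = float(rng.uniform(*params.age_range))
        gender = "male" if rng.uniform() < params.male_fraction else "female"

        skeleton = build_trial_list(params.task, rng)
        bp = overrides.get(i, params.behavior)
        trial_log = simulate_behavior(skeleton, params.task, bp, rng)
        effects = draw_subject_effects(latent[0], params.erp,
                                       params.coupling_p3d_happy, rng)
        raw, truth = (make_session(trial_log, effects, params, rng)
                      if params.make_eeg else (None, []))
        recog = simulate_recognition(latent[0], params.recognition, rng)
        yield SyntheticSubject(
            subject_id=f"sub-{i + 1:03d}", age=age, gender=gender,
            latents={"de": float(latent[0]), "anxiety": float(latent[1]),
                     "depression": float(latent[2])},
            cheat_items=cheat, rcads_items=np.concatenate([anx, dep]),
            trial_log=trial_log, effects=effects, raw=raw, ground_truth=truth,
            recognition=recog)
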