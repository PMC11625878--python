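"""Adaptive emotional Go/NoGo task: trial schedule and adaptation dynamics.

The task shows face photographs; gender is the Go/NoGo cue (respond to one
gender, withhold to the other) while facial emotion (angry / neutral /
happy) is task-irrelevant.  Go-stimulus display duration adapts to
performance: it shortens by 50 ms after every run of three consecutive
correct responses and lengthens by 150 ms after three consecutive
incorrect responses on NoGo trials.  The NoGo response window is 200 ms
longer than the Go window so that a non-response is demonstrably
deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from emogo.core import EMOTIONS

#: Columns of a trial log (one row per presented trial).
TRIAL_COLUMNS = [
    "trial_id", "block", "is_practice", "condition", "emotion", "identity",
    "go_duration_ms", "response_window_ms", "responded", "rt_ms", "correct",
]

OUTCOMES = ("go_correct", "go_incorrect", "nogo_correct", "nogo_incorrect")


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of the adaptive emotional Go/NoGo schedule.

    Defaults reproduce the study task: 2 blocks of 72 trials (48 Go + 24
    NoGo), three emotions balanced within condition, 20 practice trials,
    initial Go duration 550 ms, -50 ms per 3 consecutive correct, +150 ms
    per 3 consecutive incorrect NoGo responses.
    """

    n_blocks: int = 2
    trials_per_block: int = 72
    go_per_block: int = 48
    nogo_per_block: int = 24
    emotions: tuple[str, ...] = EMOTIONS
    female_models: tuple[str, ...] = ("f1", "f2", "f3", "f4")
    male_models: tuple[str, ...] = ("m1", "m2", "m3", "m4")
    go_gender: str = "male"            # counterbalance cue
    practice_trials: int = 20
    initial_go_duration_ms: float = 550.0
    dec_step_ms: float = 50.0
    inc_step_ms: float = 150.0
    correct_run_len: int = 3
    incorrect_run_len: int = 3
    nogo_window_extra_ms: float = 200.0
    min_duration_ms: float = 200.0
    max_duration_ms: float = 1300.0
    #: if True only correct Go responses feed the correct-run counter
    correct_counts_go_only: bool = False
    #: whether adaptation operates during practice trials
    adapt_during_practice: bool = False

    def __post_init__(self) -> None:
        if self.go_per_block + self.nogo_per_block != self.trials_per_block:
            raise ValueError("go_per_block + nogo_per_block must equal trials_per_block")
        k = len(self.emotions)
        if self.go_per_block % k or self.nogo_per_block % k:
            raise ValueError("per-block Go and NoGo counts must divide by the number of emotions")
        if not (self.min_duration_ms <= self.initial_go_duration_ms <= self.max_duration_ms):
            raise ValueError("initial duration must lie within the clamp bounds")
        if self.go_gender not in ("male", "female"):
            raise ValueError("go_gender must be 'male' or 'female'")

    @property
    def go_models(self) -> tuple[str, ...]:
        return self.male_models if self.go_gender == "male" else self.female_models

    @property
    def nogo_models(self) -> tuple[str, ...]:
        return self.female_models if self.go_gender == "male" else self.male_models

    @property
    def all_models(self) -> tuple[str, ...]:
        return self.female_models + self.male_models


@dataclass(frozen=True)
class AdaptState:
    """Running state of the display-duration staircase."""

    current_duration_ms: float
    consecutive_correct: int = 0
    consecutive_nogo_incorrect: int = 0

    def __post_init__(self) -> None:
        if self.consecutive_correct < 0 or self.consecutive_nogo_incorrect < 0:
            raise ValueError("run counters must be non-negative")


def response_window(condition: str, go_duration_ms: float, spec: TaskSpec) -> float:
    """Response window in ms: Go = display duration, NoGo = duration + 200 ms."""
    if condition == "Go":
        return float(go_duration_ms)
    if condition == "NoGo":
        return float(go_duration_ms) + spec.nogo_window_extra_ms
    raise ValueError(f"unknown condition {condition!r}")


def update_adaptation(state: AdaptState, trial_outcome: str, spec: TaskSpec) -> AdaptState:
    """Advance the staircase by one trial outcome.

    A run of ``correct_run_len`` consecutive correct responses shortens
    the Go display by ``dec_step_ms``; a run of ``incorrect_run_len``
    consecutive incorrect NoGo responses lengthens it by ``inc_step_ms``.
    Both counters reset on any outcome that breaks their run, and the
    triggering counter resets when its adjustment fires.  The duration is
    clamped to ``[min_duration_ms, max_duration_ms]``.
    """
    if trial_outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {trial_outcome!r}")
    dur = state.current_duration_ms
    n_corr = state.consecutive_correct
    n_bad = state.consecutive_nogo_incorrect

    is_correct = trial_outcome.endswith("_correct")
    counts_for_correct = is_correct and (
        not spec.correct_counts_go_only or trial_outcome == "go_correct"
    )

    if is_correct:
        n_bad = 0
        n_corr = n_corr + 1 if counts_for_correct else 0
        if n_corr >= spec.correct_run_len:
            dur -= spec.dec_step_ms
            n_corr = 0
    else:
        n_corr = 0
        n_bad = n_bad + 1 if trial_outcome == "nogo_incorrect" else 0
        if n_bad >= spec.incorrect_run_len:
            dur += spec.inc_step_ms
            n_bad = 0

    dur = min(max(dur, spec.min_duration_ms), spec.max_duration_ms)
    return AdaptState(dur, n_corr, n_bad)


def _block_skeleton(spec: TaskSpec, rng: np.random.Generator,
                    n_go: int, n_nogo: int, prev_identity: str | None,
                    max_retries: int = 1000) -> tuple[list[tuple[str, str, str]], str]:
    """One block of (condition, emotion, identity) with balance + adjacency.

    Emotions are balanced exactly within each condition; no two consecutive
    trials (including across the block boundary) share a face identity.
    """
    k = len(spec.emotions)
    cells = (
        [("Go", e) for e in spec.emotions for _ in range(n_go // k)]
        + [("NoGo", e) for e in spec.emotions for _ in range(n_nogo // k)]
    )
    order = rng.permutation(len(cells))
    seq = [cells[i] for i in order]

    trials: list[tuple[str, str, str]] = []
    prev = prev_identity
    for cond, emo in seq:
        pool = spec.go_models if cond == "Go" else spec.nogo_models
        choices = [m for m in pool if m != prev]
        if not choices:
            raise ValueError(
                "identity adjacency constraint infeasible: need at least two "
                "face models per gender"
            )
        ident = choices[int(rng.integers(len(choices)))]
        trials.append((cond, emo, ident))
        prev = ident
    return trials, prev


def build_trial_list(spec: TaskSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Build the pre-response trial skeleton for a whole session.

    Returns a trial log DataFrame (``TRIAL_COLUMNS``) with response fields
    unset (NaN / None); ``simulate_behavior`` or a real session fills them.
    Deterministic for a fixed ``(spec, seed)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[dict] = []
    prev: str | None = None
    trial_id = 0

    if spec.practice_trials:
        # practice keeps the Go:NoGo ratio approximately and cycles emotions
        n_go_p = int(round(spec.practice_trials * spec.go_per_block / spec.trials_per_block))
        n_nogo_p = spec.practice_trials - n_go_p
        conds = ["Go"] * n_go_p + ["NoGo"] * n_nogo_p
        order = rng.permutation(len(conds))
        for j, i in enumerate(order):
            cond = conds[i]
            emo = spec.emotions[j % len(spec.emotions)]
            pool = spec.go_models if cond == "Go" else spec.nogo_models
            choices = [m for m in pool if m != prev]
            if not choices:
                raise ValueError("identity adjacency constraint infeasible")
            ident = choices[int(rng.integers(len(choices)))]
            rows.append(dict(trial_id=trial_id, block=0, is_practice=True,
                             condition=cond, emotion=emo, identity=ident))
            prev = ident
            trial_id += 1

    for block in range(1, spec.n_blocks + 1):
        trials, prev = _block_skeleton(spec, rng, spec.go_per_block, spec.nogo_per_block, prev)
        for cond, emo, ident in trials:
            rows.append(dict(trial_id=trial_id, block=block, is_practice=False,
                             condition=cond, emotion=emo, identity=ident))
            trial_id += 1

    df = pd.DataFrame(rows)
    for col in ("go_duration_ms", "response_window_ms", "rt_ms"):
        df[col] = np.nan
    df["responded"] = pd.array([pd.NA] * len(df), dtype="boolean")
    df["correct"] = pd.array([pd.NA] * len(df), dtype="boolean")
    return df[TRIAL_COLUMNS]


def trial_outcome(condition: str, correct: bool) -> str:
    """Map a trial's condition/correctness to a staircase outcome token."""
    return f"{'go' if condition == 'Go' else 'nogo'}_{'correct' if correct else 'incorrect'}"
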