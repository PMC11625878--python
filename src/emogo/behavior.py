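"""Behavioral scoring: Go/NoGo performance and the emotion-sorting task.

Go/NoGo scoring applies the deliberate-response rule: only responses with
200 ms <= RT <= 1200 ms count as responses; anything outside that band is
treated as non-deliberate and discarded before accuracy and RT are
computed.  NoGo RT is the mean RT of commission errors (the only NoGo
responses that exist).

The emotion-recognition task asks children to sort 66 printed cards (two
models x [3 emotions x 10 morph intensities + 3 neutral faces]) into
happy / angry / sad / neutral boxes; accuracy per emotion is out of 20
cards, and the overall score is the unweighted mean of the three emotion
accuracies (neutral cards are scored separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DELIBERATE_RT_MS = (200.0, 1200.0)
RECOGNITION_EMOTIONS = ("happy", "angry", "sad")


@dataclass
class BehaviorSummary:
    """Per-subject Go/NoGo scores, overall and per emotion.

    ``table`` is indexed by 'overall' + emotions with columns
    go_accuracy, nogo_accuracy, go_rt_ms, nogo_rt_ms, n_go, n_nogo.
    ``overall_accuracy`` pools Go and NoGo trials (used for the <50%
    exclusion rule).
    """

    table: pd.DataFrame
    overall_accuracy: float
    excluded_response_mode: str

    @property
    def go_accuracy(self) -> float:
        return float(self.table.loc["overall", "go_accuracy"])

    @property
    def nogo_accuracy(self) -> float:
        return float(self.table.loc["overall", "nogo_accuracy"])


def _deliberate(df: pd.DataFrame) -> pd.Series:
    lo, hi = DELIBERATE_RT_MS
    resp = df["responded"].fillna(False).astype(bool)
    return resp & df["rt_ms"].between(lo, hi)


def score_gonogo(trial_log: pd.DataFrame, excluded_response: str = "omission") -> BehaviorSummary:
    """Score a completed trial log (practice trials are ignored).

    ``excluded_response`` controls the Go denominator when a response falls
    outside the deliberate window: ``"omission"`` (default) keeps the trial
    and counts it as a miss; ``"drop"`` removes the trial from the
    denominator entirely.
    """
    if excluded_response not in ("omission", "drop"):
        raise ValueError("excluded_response must be 'omission' or 'drop'")
    df = trial_log.loc[~trial_log["is_practice"].astype(bool)].copy()
    if df.empty:
        raise ValueError("trial log contains no scoreable (non-practice) trials")

    df["deliberate"] = _deliberate(df)
    df["nondeliberate_resp"] = df["responded"].fillna(False).astype(bool) & ~df["deliberate"]

    def cell(sub: pd.DataFrame) -> dict:
        go = sub[sub["condition"] == "Go"]
        nogo = sub[sub["condition"] == "NoGo"]
        if excluded_response == "drop":
            go = go[~go["nondeliberate_resp"]]
        n_go, n_nogo = len(go), len(nogo)
        go_hits = int(go["deliberate"].sum())
        commissions = nogo[nogo["deliberate"]]
        go_acc = 100.0 * go_hits / n_go if n_go else np.nan
        nogo_acc = 100.0 * (n_nogo - len(commissions)) / n_nogo if n_nogo else np.nan
        return dict(
            go_accuracy=go_acc,
            nogo_accuracy=nogo_acc,
            go_rt_ms=float(go.loc[go["deliberate"], "rt_ms"].mean()) if go_hits else np.nan,
            nogo_rt_ms=float(commissions["rt_ms"].mean()) if len(commissions) else np.nan,
            n_go=n_go, n_nogo=n_nogo,
        )

    rows = {"overall": cell(df)}
    for emo in sorted(df["emotion"].unique()):
        rows[emo] = cell(df[df["emotion"] == emo])
    table = pd.DataFrame(rows).T

    # pooled accuracy over all trials (for the accuracy<50% exclusion rule)
    go = df[df["condition"] == "Go"]
    if excluded_response == "drop":
        go = go[~go["nondeliberate_resp"]]
    nogo = df[df["condition"] == "NoGo"]
    n_correct = int(go["deliberate"].sum()) + int((~_deliberate(nogo)).sum())
    overall = 100.0 * n_correct / (len(go) + len(nogo))
    return BehaviorSummary(table=table, overall_accuracy=overall,
                           excluded_response_mode=excluded_response)


def build_morph_inventory(models: tuple[str, ...] = ("m09", "m10"),
                          emotions: tuple[str, ...] = RECOGNITION_EMOTIONS,
                          levels: int = 10,
                          n_neutral_per_model: int = 3) -> pd.DataFrame:
    """Card inventory for the sorting task.

    Each model contributes ``len(emotions) * levels`` morph cards (intensity
    10%..100% in equal steps) plus ``n_neutral_per_model`` neutral cards:
    33 cards per model at the defaults, i.e. 20 scoreable cards per emotion
    across the two models.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rows = []
    for model in models:
        for emo in emotions:
            for lv in range(1, levels + 1):
                intensity = lv / levels
                rows.append(dict(card_id=f"{model}_{emo}_{int(round(100 * intensity)):03d}",
                                 model=model, true_label=emo, intensity=intensity))
        for j in range(1, n_neutral_per_model + 1):
            rows.append(dict(card_id=f"{model}_neutral_{j}", model=model,
                             true_label="neutral", intensity=0.0))
    return pd.DataFrame(rows)


@dataclass
class RecognitionSummary:
    """Accuracy (%) per emotion (out of 20 cards), overall mean, neutral."""

    accuracy: dict[str, float]   # emotion -> %
    overall: float
    neutral_accuracy: float
    n_cards: dict[str, int]


def score_recognition(record: pd.DataFrame,
                      inventory: pd.DataFrame | None = None) -> RecognitionSummary:
    """Score a sorting record (columns card_id, chosen_label).

    The record must cover the full inventory; missing cards raise an error
    naming them.  Overall accuracy averages the three emotion accuracies;
    neutral cards are scored separately and excluded from the overall mean.
    """
    inv = build_morph_inventory() if inventory is None else inventory
    merged = inv.merge(record[["card_id", "chosen_label"]], on="card_id", how="left")
    missing = merged.loc[merged["chosen_label"].isna(), "card_id"].tolist()
    if missing:
        raise ValueError(f"incomplete sorting record; missing cards: {missing}")
    merged["correct"] = merged["chosen_label"] == merged["true_label"]

    acc: dict[str, float] = {}
    n_cards: dict[str, int] = {}
    emotions = [e for e in merged["true_label"].unique() if e != "neutral"]
    for emo in sorted(emotions):
        sub = merged[merged["true_label"] == emo]
        acc[emo] = 100.0 * sub["correct"].mean()
        n_cards[emo] = len(sub)
    neutral = merged[merged["true_label"] == "neutral"]
    neutral_acc = 100.0 * neutral["correct"].mean() if len(neutral) else np.nan
    overall = float(np.mean([acc[e] for e in sorted(emotions)]))
    return RecognitionSummary(accuracy=acc, overall=overall,
                              neutral_accuracy=float(neutral_acc), n_cards=n_cards)
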