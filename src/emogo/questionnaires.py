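"""Questionnaire scoring: ChEAT (26 items) and RCADS-25, plus utilities.

The ChEAT measures disordered-eating attitudes on a six-option frequency
scale.  Two scoring strategies are implemented:

* ``traditional`` — the three most symptomatic options (often / very
  often / always) score 1-3, the rest 0; totals range 0-78.
* ``alternative`` — all six options map to 1-6 in scale order and are
  summed; totals range 26-156.  This spreads variance across the low end
  of the scale, which matters in community samples where most children
  endorse little symptomatology.

The RCADS-25 has 15 anxiety and 10 depression items on a four-option
scale scored 0-3 (anxiety totals 0-45, depression 0-30).

Note on option wording: published descriptions of the alternative ChEAT
anchors are inconsistent about whether the scale ends at "very often" or
"always".  This package orders the canonical option set
never < very rarely < rarely < often < very often < always and maps it to
1..6; pass ``option_order`` to change this.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

CHEAT_OPTIONS: tuple[str, ...] = (
    "never", "very rarely", "rarely", "often", "very often", "always",
)
RCADS_OPTIONS: tuple[str, ...] = ("never", "sometimes", "often", "always")

N_CHEAT_ITEMS = 26
N_RCADS_ITEMS = 25
#: Package convention for the 15/10 subscale partition (0-based item indices).
RCADS_ANXIETY_ITEMS: tuple[int, ...] = tuple(range(15))
RCADS_DEPRESSION_ITEMS: tuple[int, ...] = tuple(range(15, 25))


def _codes(responses: Sequence, options: tuple[str, ...], n_items: int) -> np.ndarray:
    """Validate responses and return 0-based option codes."""
    if len(responses) != n_items:
        raise ValueError(f"expected {n_items} item responses, got {len(responses)}")
    codes = np.empty(n_items, dtype=int)
    for i, r in enumerate(responses):
        if r is None or (isinstance(r, float) and math.isnan(r)):
            raise ValueError(f"missing response for item {i + 1}; no imputation is performed")
        if isinstance(r, str):
            try:
                codes[i] = options.index(r)
            except ValueError:
                raise ValueError(f"item {i + 1}: unknown option {r!r}") from None
        else:
            c = int(r)
            if not 0 <= c < len(options):
                raise ValueError(f"item {i + 1}: code {c} outside 0..{len(options) - 1}")
            codes[i] = c
    return codes


def score_cheat(responses: Sequence, method: str = "alternative",
                option_order: tuple[str, ...] = CHEAT_OPTIONS,
                reverse_mask: Sequence[bool] | None = None) -> int:
    """Total ChEAT score under the traditional or alternative strategy.

    ``responses`` are 26 option labels (or 0-based codes in scale order).
    ``reverse_mask`` optionally reverse-scores flagged items (default none).
    """
    codes = _codes(responses, option_order, N_CHEAT_ITEMS)
    if reverse_mask is not None:
        mask = np.asarray(reverse_mask, dtype=bool)
        if mask.shape != (N_CHEAT_ITEMS,):
            raise ValueError("reverse_mask must have 26 entries")
        codes = np.where(mask, len(option_order) - 1 - codes, codes)
    if method == "alternative":
        return int(np.sum(codes + 1))
    if method == "traditional":
        return int(np.sum(np.clip(codes - 2, 0, None)))
    raise ValueError(f"unknown scoring method {method!r}")


def score_rcads(responses: Sequence,
                anxiety_items: Sequence[int] = RCADS_ANXIETY_ITEMS,
                depression_items: Sequence[int] = RCADS_DEPRESSION_ITEMS,
                ) -> tuple[int, int]:
    """(anxiety total, depression total) from 25 RCADS item responses."""
    anx, dep = set(anxiety_items), set(depression_items)
    if anx & dep or len(anx) != 15 or len(dep) != 10:
        raise ValueError("subscale map must partition the 25 items into 15 + 10")
    codes = _codes(responses, RCADS_OPTIONS, N_RCADS_ITEMS)
    return (int(codes[sorted(anx)].sum()), int(codes[sorted(dep)].sum()))


def log10_plus1(x) -> np.ndarray | float:
    """Log10(x + 1) normality transform for non-negative scores."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log10_plus1 requires non-negative input")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an (n_respondents, k_items) score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals).
    Raises if the total-score variance is zero (alpha undefined).
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
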