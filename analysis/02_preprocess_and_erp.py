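#!/usr/bin/env python
"""Preprocess every session and extract N2/P3 difference scores.

Regenerates the cohort of 01_simulate_cohort.py, runs each subject's EEG
through the cleaning chain (0.3-100 Hz band-pass, average reference,
±200 µV threshold marking, blink detection at Fp1/Fp2, 30 Hz low-pass),
epochs -100..1000 ms around stimulus onsets, and scores mean amplitudes
at Fz (N2 300-400 ms, P3 480-600 ms) per condition x emotion.

Writes ``results/erp_summary.csv`` (per subject x cell) and
``results/grand_average_fz.csv`` (grand-mean waveforms per condition x
emotion, the package's analogue of a grand-average figure).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from emogo.config import RunConfig
from emogo.erp import average_erp, baseline_correct, difference_scores, epoch, summarize_erp
from emogo.preprocess import clean_pipeline
from emogo.synth import GeneratorParams, iter_cohort

COHORT_SEED = 20240
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = GeneratorParams(n_subjects=53, seed=COHORT_SEED)
    cfg = RunConfig(seed=COHORT_SEED, task=params.task, generator=params)
    pp, ep = cfg.preprocess, cfg.erp

    cell_rows, diff_rows = [], []
    grand = {}
    n_kept = 0
    for sub in iter_cohort(params):
        clean = clean_pipeline(sub.raw, bp_low=pp.bp_low_hz, bp_high=pp.bp_high_hz,
                               threshold_uv=pp.threshold_uv, pad_ms=pp.pad_ms,
                               lp_cutoff=pp.lp_cutoff_hz)
        eps = baseline_correct(epoch(clean, sub.trial_log))
        summary = difference_scores(summarize_erp(eps))
        for _, r in summary.cells.iterrows():
            cell_rows.append(dict(subject_id=sub.subject_id, **r))
        for _, r in summary.diffs.iterrows():
            diff_rows.append(dict(subject_id=sub.subject_id, **r))
        fz = eps.channel_index("Fz")
        for cond in ("Go", "NoGo"):
            for emo in ("angry", "neutral", "happy"):
                wave, n = average_erp(eps, cond, emo)
                if wave is not None:
                    grand.setdefault((cond, emo), []).append(wave[fz])
        times = eps.times_ms
        n_kept += 1

    cells = pd.DataFrame(cell_rows)
    cells.to_csv(RESULTS / "erp_summary.csv", index=False)
    pd.DataFrame(diff_rows).to_csv(RESULTS / "erp_differences.csv", index=False)

    ga = pd.DataFrame({"time_ms": times})
    for (cond, emo), waves in sorted(grand.items()):
        ga[f"{cond.lower()}_{emo}"] = np.mean(waves, axis=0)
    ga.round(4).to_csv(RESULTS / "grand_average_fz.csv", index=False)

    valid = cells.groupby(["condition", "emotion"])["n_valid"].agg(["mean", "min", "max"])
    print(f"processed {n_kept} subjects; valid-trial counts per cell:")
    print(valid.round(2).to_string())
    print(f"wrote {RESULTS}/erp_summary.csv, erp_differences.csv, grand_average_fz.csv")


if __name__ == "__main__":
    main()
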