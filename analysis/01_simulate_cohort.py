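#!/usr/bin/env python
"""Simulate the study cohort and write its raw artifacts.

Generates the default 53-child synthetic study (adaptive emotional
Go/NoGo task; ChEAT and RCADS-25 item responses; emotion-sorting
records) and writes:

* ``results/cohort/questionnaires.csv`` — item-level responses;
* ``results/cohort/trial_log_summary.csv`` — per-subject trial counts and
  staircase summary.

The cohort (including the EEG sessions) is regenerated deterministically
from COHORT_SEED by the downstream scripts, so the bulky continuous
recordings are not persisted here; ``emogo simulate --out <dir>`` writes
full BrainVision session triplets with ground-truth annotations when an
on-disk study is wanted.
"""

from pathlib import Path

import dataclasses
import pandas as pd

from emogo.synth import GeneratorParams, iter_cohort

COHORT_SEED = 20240
RESULTS = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    params = GeneratorParams(n_subjects=53, seed=COHORT_SEED)
    RESULTS.mkdir(parents=True, exist_ok=True)

    qrows, trows = [], []
    for sub in iter_cohort(dataclasses.replace(params, make_eeg=False)):
        qrows.append(dict(subject_id=sub.subject_id,
                          **{f"cheat_{i + 1:02d}": int(v)
                             for i, v in enumerate(sub.cheat_items)},
                          **{f"rcads_{i + 1:02d}": int(v)
                             for i, v in enumerate(sub.rcads_items)}))
        log = sub.trial_log[~sub.trial_log["is_practice"].astype(bool)]
        trows.append(dict(
            subject_id=sub.subject_id, n_trials=len(log),
            n_go=(log["condition"] == "Go").sum(),
            n_nogo=(log["condition"] == "NoGo").sum(),
            final_go_duration_ms=log["go_duration_ms"].iloc[-1],
            mean_go_duration_ms=round(log["go_duration_ms"].mean(), 1)))

    pd.DataFrame(qrows).to_csv(RESULTS / "questionnaires.csv", index=False)
    pd.DataFrame(trows).to_csv(RESULTS / "trial_log_summary.csv", index=False)
    print(f"simulated {len(qrows)} subjects (seed {COHORT_SEED})")
    print(f"wrote {RESULTS}/questionnaires.csv and trial_log_summary.csv")


if __name__ == "__main__":
    main()
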