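#!/usr/bin/env python
"""Dimensional inference on the scored subject table.

Reads ``results/subject_table.csv`` (from 03_score_subjects.py) and runs
the correlation and regression layer:

* sensitivity: the critical r for this sample size at alpha=.05;
* Pearson correlations of ChEAT / RCADS (Log10(+1)-transformed) with the
  per-emotion P3d and N2d difference scores (age as covariate), with
  Bonferroni correction over the 3-emotion family;
* behavioral and recognition correlations (gender as covariate);
* hierarchical regression of ChEAT on anxiety + depression (step 1) and
  P3d(happy) (step 2), with the R²-change F test and VIFs.

Writes ``results/correlations_*.csv`` and ``results/regression.txt``.
"""

from pathlib import Path

import pandas as pd

from emogo import stats as st
from emogo.pipeline import format_regression

RESULTS = Path(__file__).resolve().parent.parent / "results"

TRAITS = ["cheat_total", "rcads_anxiety_log", "rcads_depression_log"]


def main() -> None:
    table = pd.read_csv(RESULTS / "subject_table.csv")
    included = table[table["included_erp"]]
    n = len(included)

    rc = st.critical_r(n, alpha=0.05)
    print(f"n = {n} ERP-included subjects; critical |r| at alpha=.05: {rc:.3f}")

    erp_corr = st.correlation_table(
        included, TRAITS, ["p3d_angry", "p3d_neutral", "p3d_happy"],
        covariates=["age"], bonferroni_m=3)
    n2_corr = st.correlation_table(
        included, TRAITS, ["n2d_angry", "n2d_neutral", "n2d_happy"],
        covariates=["age"], bonferroni_m=3)
    beh = table[table["included_behavior"]]
    beh_corr = st.correlation_table(
        beh, TRAITS, ["go_accuracy", "nogo_accuracy", "go_rt_ms", "nogo_rt_ms"],
        covariates=["gender_male"], bonferroni_m=4)
    rec_corr = st.correlation_table(
        beh, TRAITS, ["recog_happy", "recog_angry", "recog_sad"],
        covariates=["gender_male"], bonferroni_m=3)

    erp_corr.to_csv(RESULTS / "correlations_p3d.csv", index=False)
    n2_corr.to_csv(RESULTS / "correlations_n2d.csv", index=False)
    beh_corr.to_csv(RESULTS / "correlations_behavior.csv", index=False)
    rec_corr.to_csv(RESULTS / "correlations_recognition.csv", index=False)

    print("\nChEAT x P3d correlations (age-adjusted, Bonferroni m=3):")
    print(erp_corr[erp_corr.x == "cheat_total"][["y", "r", "p", "significant"]]
          .round(3).to_string(index=False))

    sub = included.dropna(subset=TRAITS + ["p3d_happy"])
    reg = st.hierarchical_regression(
        sub["cheat_total"].to_numpy(),
        sub[["rcads_anxiety_log", "rcads_depression_log"]], sub[["p3d_happy"]])
    report = format_regression(reg)
    (RESULTS / "regression.txt").write_text(report, encoding="utf-8")
    print("\nHierarchical regression (ChEAT ~ anxiety + depression, + P3d happy):")
    print(report)
    print(f"wrote correlation tables and regression report under {RESULTS}/")


if __name__ == "__main__":
    main()
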