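"""End-to-end study orchestration.

``run_study`` executes generate -> preprocess -> ERP extraction ->
behavior/questionnaire scoring -> QC -> inference in a fixed order and
returns a ``StudyResult`` (per-subject table, correlation tables,
hierarchical regression, exclusion log, config snapshot).  ``process_subject``
is the per-subject worker the acceptance and analysis scripts reuse.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emogo import behavior as beh
from emogo import erp as erpmod
from emogo import questionnaires as q
from emogo import stats as st
from emogo.config import RunConfig, config_to_dict, save_config
from emogo.io_brainvision import file_sha256, write_brainvision, write_subject_table
from emogo.preprocess import clean_pipeline
from emogo.synth import GeneratorParams, SyntheticSubject, generate_cohort

ERP_MEASURES = ["p3d_angry", "p3d_neutral", "p3d_happy",
                "n2d_angry", "n2d_neutral", "n2d_happy"]
BEHAVIOR_MEASURES = ["go_accuracy", "nogo_accuracy", "go_rt_ms", "nogo_rt_ms"]
RECOG_MEASURES = ["recog_happy", "recog_angry", "recog_sad"]


@dataclass
class StudyResult:
    subject_table: pd.DataFrame
    erp_correlations: pd.DataFrame
    behavior_correlations: pd.DataFrame
    recognition_correlations: pd.DataFrame
    regression: st.HierRegressionResult | None
    exclusions: pd.DataFrame
    config: dict
    seed: int


def process_subject(sub: SyntheticSubject, cfg: RunConfig) -> dict:
    """Score one subject end to end; returns a tidy row (dict)."""
    pp, ep = cfg.preprocess, cfg.erp
    row: dict = dict(subject_id=sub.subject_id, age=sub.age,
                     gender=sub.gender, gender_male=float(sub.gender == "male"))

    row["cheat_total"] = q.score_cheat(sub.cheat_items, method="alternative")
    row["cheat_traditional"] = q.score_cheat(sub.cheat_items, method="traditional")
    anx, dep = q.score_rcads(sub.rcads_items)
    row["rcads_anxiety"], row["rcads_depression"] = anx, dep
    row["rcads_anxiety_log"] = q.log10_plus1(float(anx))
    row["rcads_depression_log"] = q.log10_plus1(float(dep))

    bsum = beh.score_gonogo(sub.trial_log)
    row["overall_accuracy"] = bsum.overall_accuracy
    for m in BEHAVIOR_MEASURES:
        row[m] = float(bsum.table.loc["overall", m])

    if sub.recognition is not None:
        rec = beh.score_recognition(sub.recognition)
        for emo in ("happy", "angry", "sad"):
            row[f"recog_{emo}"] = rec.accuracy.get(emo, np.nan)
        row["recog_overall"] = rec.overall

    if sub.raw is not None:
        clean = clean_pipeline(
            sub.raw, bp_low=pp.bp_low_hz, bp_high=pp.bp_high_hz,
            threshold_uv=pp.threshold_uv, pad_ms=pp.pad_ms, lp_cutoff=pp.lp_cutoff_hz,
            blink_kwargs=dict(min_rise_ms=pp.blink_min_rise_ms,
                              min_fall_ms=pp.blink_min_fall_ms,
                              min_amp_uv=pp.blink_min_amp_uv,
                              prescreen_uv=pp.blink_prescreen_uv))
        eps = erpmod.epoch(clean, sub.trial_log, tmin_ms=ep.tmin_ms, tmax_ms=ep.tmax_ms,
                           anticipatory_rt_ms=ep.anticipatory_rt_ms)
        eps = erpmod.baseline_correct(eps)
        summary = erpmod.summarize_erp(eps, correct_only=ep.correct_only,
                                       n2_window=ep.n2_window_ms,
                                       p3_window=ep.p3_window_ms, channel=ep.channel)
        summary = erpmod.difference_scores(summary)
        for _, r in summary.diffs.iterrows():
            row[f"p3d_{r.emotion}"] = r.p3d_uv
            row[f"n2d_{r.emotion}"] = r.n2d_uv
        for _, r in summary.cells.iterrows():
            row[f"n_valid_{r.condition.lower()}_{r.emotion}"] = int(r.n_valid)
        qc = erpmod.subject_qc(summary, bsum.overall_accuracy,
                               min_trials=ep.min_trials, min_accuracy=ep.min_accuracy)
    else:
        qc = erpmod.subject_qc(
            erpmod.ErpSummary(cells=pd.DataFrame(
                dict(condition=[], emotion=[], n2_uv=[], p3_uv=[],
                     n_valid=pd.Series([], dtype=int)))),
            bsum.overall_accuracy, min_trials=0, min_accuracy=ep.min_accuracy)

    row["included_behavior"] = qc.included_behavior
    row["included_erp"] = qc.included_erp and sub.raw is not None
    row["exclusion_reasons"] = "; ".join(qc.reasons)
    return row


def run_study(cfg: RunConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full pipeline on a synthetic cohort.

    Subjects are generated and scored one at a time so memory stays
    bounded regardless of cohort size.
    """
    from emogo.synth import iter_cohort

    rows = [process_subject(s, cfg) for s in iter_cohort(cfg.resolved_generator())]
    table = pd.DataFrame(rows)

    sp = cfg.stats
    trait_vars = ["cheat_total", "rcads_anxiety_log" if sp.transform_rcads else "rcads_anxiety",
                  "rcads_depression_log" if sp.transform_rcads else "rcads_depression"]

    beh_ok = table[table["included_behavior"]]
    erp_ok = table[table["included_erp"]] if table["included_erp"].any() else table.iloc[0:0]

    def corr(frame, y_vars, covs):
        if len(frame) < 5 + len(covs):
            return pd.DataFrame(columns=["x", "y", "r", "n", "df", "t", "p",
                                         "corrected_alpha", "significant", "covariates"])
        return st.correlation_table(frame, trait_vars, y_vars,
                                    covariates=list(covs), alpha=sp.alpha,
                                    bonferroni_m=3)

    erp_corr = corr(erp_ok, ["p3d_angry", "p3d_neutral", "p3d_happy"], sp.erp_covariates) \
        if len(erp_ok) else pd.DataFrame()
    beh_corr = corr(beh_ok, BEHAVIOR_MEASURES[:2], sp.behavior_covariates)
    rec_corr = corr(beh_ok, RECOG_MEASURES, sp.behavior_covariates) \
        if "recog_happy" in table.columns else pd.DataFrame()

    regression = None
    if len(erp_ok) >= 10 and "p3d_happy" in erp_ok.columns:
        sub = erp_ok.dropna(subset=["cheat_total", trait_vars[1], trait_vars[2], "p3d_happy"])
        regression = st.hierarchical_regression(
            sub["cheat_total"].to_numpy(),
            sub[[trait_vars[1], trait_vars[2]]],
            sub[["p3d_happy"]], alpha=sp.alpha)

    excl = table.loc[~table["included_behavior"] | ~table["included_erp"],
                     ["subject_id", "included_behavior", "included_erp", "exclusion_reasons"]]
    result = StudyResult(subject_table=table, erp_correlations=erp_corr,
                         behavior_correlations=beh_corr,
                         recognition_correlations=rec_corr, regression=regression,
                         exclusions=excl.reset_index(drop=True),
                         config=config_to_dict(cfg), seed=cfg.seed)
    if out_dir is not None:
        _write_result(result, cfg, Path(out_dir))
    return result


def _write_result(res: StudyResult, cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_subject_table(res.subject_table, out / "subject_table.csv")
    res.erp_correlations.to_csv(out / "erp_correlations.csv", index=False)
    res.behavior_correlations.to_csv(out / "behavior_correlations.csv", index=False)
    res.recognition_correlations.to_csv(out / "recognition_correlations.csv", index=False)
    res.exclusions.to_csv(out / "exclusions.csv", index=False)
    save_config(cfg, out / "config.yaml")
    if res.regression is not None:
        with open(out / "regression.txt", "w", encoding="utf-8") as fh:
            fh.write(format_regression(res.regression))


def format_regression(reg: st.HierRegressionResult) -> str:
    """Human-readable two-step regression report."""
    lines = []
    for i, step in enumerate(reg.steps, start=1):
        lines.append(f"Step {i}:  R^2 = {step.r2:.3f}   F({step.df_model}, "
                     f"{step.df_resid}) = {step.f:.2f}, p = {step.f_p:.4g}")
        lines.append(step.coef.to_string(float_format=lambda v: f"{v: .3f}"))
        lines.append("")
    q_, dfr = reg.delta_df
    lines.append(f"Delta R^2 = {reg.delta_r2:.3f}   Delta F({q_}, {dfr}) = "
                 f"{reg.delta_f:.2f}, p = {reg.delta_f_p:.4g}")
    lines.append("VIF (full model):")
    lines.append(reg.vif.to_string(float_format=lambda v: f"{v: .2f}"))
    return "\n".join(lines) + "\n"


def make_fixtures(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write a complete on-disk synthetic study with a checksum manifest.

    Per subject: BrainVision session triplet, trial-log CSV, questionnaire
    CSV, and ground-truth span JSON.
    """
    from emogo.synth import iter_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    qrows = []
    for sub in iter_cohort(cfg.resolved_generator()):
        sdir = out / sub.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        if sub.raw is not None:
            for p in write_brainvision(sub.raw, sdir / "session"):
                manifest[str(p.relative_to(out))] = file_sha256(p)
            truth = [dataclasses.asdict(s) for s in sub.ground_truth]
            gt = sdir / "ground_truth.json"
            gt.write_text(json.dumps(truth, indent=1), encoding="utf-8")
            manifest[str(gt.relative_to(out))] = file_sha256(gt)
        tl = sdir / "trials.csv"
        sub.trial_log.to_csv(tl, index=False)
        manifest[str(tl.relative_to(out))] = file_sha256(tl)
        qrows.append(dict(subject_id=sub.subject_id,
                          **{f"cheat_{i + 1:02d}": int(v) for i, v in enumerate(sub.cheat_items)},
                          **{f"rcads_{i + 1:02d}": int(v) for i, v in enumerate(sub.rcads_items)}))
    qpath = out / "questionnaires.csv"
    pd.DataFrame(qrows).to_csv(qpath, index=False)
    manifest[str(qpath.relative_to(out))] = file_sha256(qpath)
    save_config(cfg, out / "config.yaml")
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return mpath


def verify_manifest(fixture_dir: str | Path) -> bool:
    """Re-hash every file listed in the manifest; True iff all match."""
    root = Path(fixture_dir)
    manifest = json.loads((root / "manifest.json").read_text(encoding="utf-8"))
    return all(file_sha256(root / rel) == digest for rel, digest in manifest.items())
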