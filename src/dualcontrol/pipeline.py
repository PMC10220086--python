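"""End-to-end orchestration: simulate -> measure -> model -> stats -> predict.

``build_features`` turns a trial table into the per-subject feature table
(SSRT per task, context effect, post-error slowing and stop-accuracy
effect, anticipation correlation, optional DDM deltas) joined with the
subject table.  ``run_pipeline`` runs the whole analysis on simulated or
loaded data and writes a reproducible bundle of CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualcontrol.dbm import DBMConfig, anticipation_correlation, calibrate_alpha, pstop_per_run
from dualcontrol.ddm import post_error_ddm
from dualcontrol.predict import FULL_FEATURES, REDUCED_FEATURES, compare_models, loocv_predict
from dualcontrol.proactive import (
    context_effect,
    label_history,
    post_error_slowing,
    post_error_stop_accuracy_effect,
)
from dualcontrol.race_model import summarize_cohort_reactive, ssrt_reliability
from dualcontrol.simulate import CohortConfig, simulate_cohort
from dualcontrol.stats import cohort_filter, fisher_z_compare, one_sample_t, welch_t
from dualcontrol.trial_data import read_subjects, read_trials

log = logging.getLogger("dualcontrol")

FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "ssrt_sst",
    "ssrt_csst",
    "context_effect",
    "pes",
    "post_error_stop_acc_effect",
    "antic_corr",
    "d_a",
    "d_v",
    "d_t0",
]


@dataclass
class RunConfig:
    """Pipeline settings; fully serialised next to every report."""

    seed: int = 7
    n_td: int = 30
    n_adhd: int = 50
    runs_per_task: int = 2
    dbm: DBMConfig = field(default_factory=DBMConfig)
    calibrate_dbm_alpha: bool = False
    with_ddm: bool = False
    apply_cohort_filter: bool = True
    outcomes: tuple[str, ...] = ("swan_inattention", "swan_hyperimpulsivity")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def build_features(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    dbm_cfg: DBMConfig | None = None,
    with_ddm: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject feature table from a validated trial table."""
    dbm_cfg = dbm_cfg or DBMConfig()
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        row: dict = {"subject_id": str(sid), "group": sub["group"].iloc[0]}
        sst = sub[sub["task"] == "SST"]
        csst = sub[sub["task"] == "CSST"]
        row["ssrt_sst"] = row["ssrt_csst"] = np.nan
        row["context_effect"] = row["pes"] = np.nan
        row["post_error_stop_acc_effect"] = row["antic_corr"] = np.nan
        row["d_a"] = row["d_v"] = row["d_t0"] = np.nan

        from dualcontrol.race_model import summarize_reactive

        if len(sst):
            row["ssrt_sst"] = summarize_reactive(sst).ssrt
            labels = label_history(sst)
            pes, _ = post_error_slowing(sst, labels)
            row["pes"] = pes
            eff, _ = post_error_stop_accuracy_effect(sst, labels)
            row["post_error_stop_acc_effect"] = eff
            p_stop = pstop_per_run(sst, dbm_cfg)
            r, _, flagged = anticipation_correlation(sst, p_stop)
            row["antic_corr"] = np.nan if flagged else r
            if with_ddm:
                delta, _, _ = post_error_ddm(sst, labels, seed=seed)
                if not delta.flagged:
                    row["d_a"], row["d_v"], row["d_t0"] = delta.d_a, delta.d_v, delta.d_t0
        if len(csst):
            row["ssrt_csst"] = summarize_reactive(csst).ssrt
            ce, _ = context_effect(csst)
            row["context_effect"] = ce
        rows.append(row)
    feats = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return feats.merge(subjects, on=["subject_id", "group"], how="left")


def _stat_dict(res) -> dict:
    return {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in vars(res).items()}


def group_statistics(features: pd.DataFrame) -> dict:
    """Group comparisons and within-cohort effects on the feature table."""
    td = features[features["group"] == "TD"]
    adhd = features[features["group"] == "ADHD"]
    report: dict = {}
    if len(td) >= 2 and len(adhd) >= 2:
        for col in (
            "ssrt_sst",
            "ssrt_csst",
            "context_effect",
            "pes",
            "post_error_stop_acc_effect",
            "antic_corr",
        ):
            a = td[col].dropna().to_numpy()
            b = adhd[col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                report[f"welch_{col}"] = _stat_dict(welch_t(a, b))
    for col in ("context_effect", "pes", "post_error_stop_acc_effect"):
        vals = features[col].dropna().to_numpy()
        if len(vals) >= 2:
            report[f"one_sample_{col}"] = _stat_dict(one_sample_t(vals))
    # correlation of each proactive measure with SSRT, per group, Fisher-Z compared
    for col in ("context_effect", "pes", "antic_corr"):
        pair = {}
        rs = {}
        for name, g in (("TD", td), ("ADHD", adhd)):
            d = g[["ssrt_sst", col]].dropna()
            if len(d) >= 4:
                from scipy import stats as sps

                r, p = sps.pearsonr(d[col], d["ssrt_sst"])
                pair[name] = {"r": float(r), "p": float(p), "n": int(len(d))}
                rs[name] = (float(r), int(len(d)))
        if set(rs) == {"TD", "ADHD"}:
            fz = fisher_z_compare(rs["TD"][0], rs["TD"][1], rs["ADHD"][0], rs["ADHD"][1])
            pair["fisher_z"] = _stat_dict(fz)
        report[f"ssrt_corr_{col}"] = pair
    both = features[["ssrt_sst", "ssrt_csst"]].dropna()
    if len(both) >= 4:
        r, p = ssrt_reliability(both["ssrt_sst"].to_numpy(), both["ssrt_csst"].to_numpy())
        report["ssrt_reliability"] = {"r": r, "p": p, "n": int(len(both))}
    return report


def prediction_report(features: pd.DataFrame, outcomes: tuple[str, ...]) -> dict:
    report: dict = {}
    for outcome in outcomes:
        try:
            full = loocv_predict(features, FULL_FEATURES, outcome)
            reduced = loocv_predict(features, REDUCED_FEATURES, outcome)
            comp = compare_models(full, reduced)
            report[outcome] = {
                "full": {"r": full.r_pred_obs, "p": full.p, "features": list(full.model_spec)},
                "reduced": {"r": reduced.r_pred_obs, "p": reduced.p},
                "comparison": _stat_dict(comp),
            }
        except ValueError as exc:
            report[outcome] = {"error": str(exc)}
            log.warning("prediction for %s skipped: %s", outcome, exc)
    return report


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    trials_path: str | Path | None = None,
    subjects_path: str | Path | None = None,
) -> dict:
    """Run the full analysis and write a reproducible report bundle.

    Without input paths a cohort is simulated from the config.  Artifacts:
    trials.csv, subjects.csv, reactive_summaries.csv, features.csv,
    report.json and config.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if trials_path is None:
        cohort_cfg = CohortConfig(
            n_td=config.n_td,
            n_adhd=config.n_adhd,
            runs_per_task=config.runs_per_task,
            seed=config.seed,
        )
        trials, subjects = simulate_cohort(cohort_cfg, out_dir=out_dir)
        log.info("simulated cohort: %d subjects", config.n_td + config.n_adhd)
    else:
        trials = read_trials(trials_path)
        subjects = read_subjects(subjects_path)

    summaries = summarize_cohort_reactive(trials)
    summaries.to_csv(out_dir / "reactive_summaries.csv", index=False)

    if config.apply_cohort_filter:
        retained, excluded = cohort_filter(summaries)
        excluded.to_csv(out_dir / "excluded_subjects.csv", index=False)
        trials = trials[trials["subject_id"].isin(retained)]
        subjects = subjects[subjects["subject_id"].isin(retained)]
        log.info("cohort filter retained %d subjects (%d excluded)", len(retained), len(excluded))

    dbm_cfg = config.dbm
    calibration = None
    if config.calibrate_dbm_alpha:
        curve, alpha = calibrate_alpha(trials, cfg=dbm_cfg)
        curve.to_csv(out_dir / "dbm_calibration.csv", index=False)
        dbm_cfg = DBMConfig(alpha=alpha, pm=dbm_cfg.pm, scale=dbm_cfg.scale, grid_size=dbm_cfg.grid_size)
        calibration = {"selected_alpha": alpha}
        log.info("DBM alpha calibrated to %.2f", alpha)

    features = build_features(trials, subjects, dbm_cfg, with_ddm=config.with_ddm, seed=config.seed)
    features.to_csv(out_dir / "features.csv", index=False)

    report = {
        "n_subjects": int(features["subject_id"].nunique()),
        "group_counts": features["group"].value_counts().to_dict(),
        "group_statistics": group_statistics(features),
        "prediction": prediction_report(features, config.outcomes),
    }
    if calibration:
        report["dbm_calibration"] = calibration

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    return report
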