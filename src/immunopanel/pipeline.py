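"""End-to-end orchestration of the three analysis stages.

Stage 1 (consistency check): per tissue, tumor-vs-normal Wilcoxon tests on
activation and checkpoint scores, and the activation-checkpoint Pearson
correlation per tissue and condition; tissues whose tumor correlation falls
below a threshold (default 0.5) are flagged for exclusion from a combined
immunogenicity score.

Stage 2 (validation): per-stratum Pearson correlation of the immunogenicity
score against the available infiltration readouts (ordinal pathology score,
in-silico/true infiltration), with the control signature run alongside as a
negative control.

Stage 3 (prediction): sum-of-ranks scoring of an on-treatment cohort and
ROC/AUC evaluation, pooled and per treatment arm, panel vs controls.

Stages with missing inputs are skipped with an explicit reason rather than
failing, because the three stages use different cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSet
from .panels import PanelDefinition, compute_control_scores, compute_panel_scores, default_panel
from .rank_predictor import CohortPrediction, predict_cohort
from .ssgsea import SsgseaParams
from .stats import correlation_by_stratum, groupwise_compare

logger = logging.getLogger(__name__)

#: minimum tumor activation-checkpoint correlation for a tissue to
#: contribute to a combined immunogenicity score
TUMOR_COUPLING_THRESHOLD = 0.5


@dataclass
class StageResult:
    name: str
    status: str  # "completed" | "skipped"
    reason: str = ""
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    #: non-serializable stage outputs (e.g. the CohortPrediction object)
    objects: dict = field(default_factory=dict)


@dataclass
class RunReport:
    consistency: StageResult | None = None
    validation: StageResult | None = None
    prediction: StageResult | None = None
    provenance: dict = field(default_factory=dict)

    def to_summary(self) -> dict:
        out = {"provenance": self.provenance}
        for name in ("consistency", "validation", "prediction"):
            stage = getattr(self, name)
            if stage is None:
                out[name] = {"status": "skipped", "reason": "stage not requested"}
            else:
                out[name] = {
                    "status": stage.status,
                    "reason": stage.reason,
                    **stage.summary,
                }
        return out


def run_consistency_check(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    panel: PanelDefinition | None = None,
    params: SsgseaParams | None = None,
    r_threshold: float = TUMOR_COUPLING_THRESHOLD,
) -> StageResult:
    """Tumor-vs-normal score comparison and activation-checkpoint coupling."""
    panel = panel or default_panel()
    conditions = set(meta["condition"])
    if conditions < {"tumor", "normal"}:
        return StageResult(
            name="consistency",
            status="skipped",
            reason=f"needs both tumor and normal samples, found {sorted(conditions)}",
        )
    scores = compute_panel_scores(matrix, panel, params)
    compare = groupwise_compare(
        scores, meta, group_key="condition", strata="tissue",
        value_columns=["activation", "checkpoint"],
    )
    meta_idx = meta.set_index("sample_id").loc[scores.index]
    corr_rows = []
    for (tissue, condition), chunk in scores.groupby(
        [meta_idx["tissue"], meta_idx["condition"]], sort=True
    ):
        table = correlation_by_stratum(
            chunk["activation"], chunk["checkpoint"],
            pd.Series(tissue, index=chunk.index),
        )
        row = table.iloc[0].to_dict()
        row.update(tissue=tissue, condition=condition)
        corr_rows.append(row)
    corr = pd.DataFrame(corr_rows)[
        ["tissue", "condition", "n", "testable", "r", "p_value", "significant"]
    ]
    tumor_r = corr[corr["condition"] == "tumor"].set_index("tissue")["r"]
    excluded = sorted(tumor_r.index[(tumor_r < r_threshold) | tumor_r.isna()])
    if excluded:
        logger.warning(
            "consistency check: tissue(s) %s excluded (tumor activation-"
            "checkpoint r < %.2f)", excluded, r_threshold,
        )
    return StageResult(
        name="consistency",
        status="completed",
        tables={"group_comparison": compare, "correlation": corr},
        summary={
            "excluded_tissues": excluded,
            "min_tumor_r": float(tumor_r.min()),
            "n_tissues": int(tumor_r.size),
        },
    )


def run_validation(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    panel: PanelDefinition | None = None,
    params: SsgseaParams | None = None,
) -> StageResult:
    """Correlate the immunogenicity score with infiltration readouts."""
    panel = panel or default_panel()
    readouts = [
        c for c in ("pathology_score", "true_infiltration")
        if c in meta.columns and meta[c].notna().any()
    ]
    if not readouts:
        return StageResult(
            name="validation",
            status="skipped",
            reason="neither pathology_score nor true_infiltration present",
        )
    scores = compute_panel_scores(matrix, panel, params)
    control = None
    if panel.control_set is not None:
        control = compute_control_scores(matrix, panel.control_set, params)
    meta_idx = meta.set_index("sample_id").loc[scores.index]
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"readouts": readouts}
    for readout in readouts:
        tables[f"immunogenicity_vs_{readout}"] = correlation_by_stratum(
            scores["immunogenicity"], meta_idx[readout], meta_idx["tissue"]
        )
        if control is not None:
            tables[f"control_vs_{readout}"] = correlation_by_stratum(
                control, meta_idx[readout], meta_idx["tissue"]
            )
        testable = tables[f"immunogenicity_vs_{readout}"].query("testable")
        summary[f"immunogenicity_vs_{readout}_min_r"] = (
            float(testable["r"].min()) if len(testable) else None
        )
    return StageResult(
        name="validation", status="completed", tables=tables, summary=summary
    )


def run_prediction(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    panel: PanelDefinition | None = None,
    controls: GeneSet | None = None,
    ranking: str = "pooled",
) -> StageResult:
    """Sum-of-ranks response prediction, panel vs controls."""
    panel = panel or default_panel()
    labelled = meta[meta["response"].isin(["responder", "non-responder"])]
    if labelled["response"].nunique() < 2:
        return StageResult(
            name="prediction",
            status="skipped",
            reason="cohort lacks both response classes",
        )
    if controls is None and panel.control_set is not None:
        controls = panel.control_set
    prediction = predict_cohort(matrix, panel, meta, controls, ranking=ranking)
    tables = {
        "scores": prediction.panel.scores.scores.to_frame(),
        "roc_points": prediction.panel.pooled.points(),
    }
    summary = {
        "panel_auc_pooled": prediction.panel.pooled.auc,
        "panel_auc_per_arm": {
            arm: r.auc for arm, r in prediction.panel.per_arm.items()
        },
        "genes_used": prediction.panel.scores.genes_used,
    }
    if prediction.control is not None:
        tables["control_scores"] = prediction.control.scores.scores.to_frame()
        tables["control_roc_points"] = prediction.control.pooled.points()
        summary["control_auc_pooled"] = prediction.control.pooled.auc
        summary["control_auc_per_arm"] = {
            arm: r.auc for arm, r in prediction.control.per_arm.items()
        }
    return StageResult(
        name="prediction", status="completed", tables=tables, summary=summary,
        objects={"prediction": prediction},
    )


def run_all(
    tissue_cohort: tuple[ExpressionMatrix, pd.DataFrame] | None,
    icb_cohort: tuple[ExpressionMatrix, pd.DataFrame] | None,
    panel: PanelDefinition | None = None,
    params: SsgseaParams | None = None,
    provenance: dict | None = None,
) -> RunReport:
    """Run every stage whose inputs are available."""
    panel = panel or default_panel()
    report = RunReport(provenance=provenance or {})
    if tissue_cohort is not None:
        m, meta = tissue_cohort
        report.consistency = run_consistency_check(m, meta, panel, params)
        report.validation = run_validation(m, meta, panel, params)
    else:
        reason = "no tumor/normal cohort supplied"
        report.consistency = StageResult("consistency", "skipped", reason)
        report.validation = StageResult("validation", "skipped", reason)
    if icb_cohort is not None:
        m, meta = icb_cohort
        report.prediction = run_prediction(m, meta, panel)
    else:
        report.prediction = StageResult(
            "prediction", "skipped", "no on-treatment cohort supplied"
        )
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write the JSON summary and every stage table as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = report.to_summary()
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    for name in ("consistency", "validation", "prediction"):
        stage = getattr(report, name)
        if stage is None or stage.status != "completed":
            continue
        for table_name, table in stage.tables.items():
            table.to_csv(out_dir / f"{name}_{table_name}.tsv", sep="\t")
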