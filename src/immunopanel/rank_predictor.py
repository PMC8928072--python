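"""Sum-of-ranks response score and its ROC/AUC evaluation.

For each panel gene, all cohort samples are ranked by that gene's expression
(rank 1 = lowest, ties averaged); a sample's score is the sum of its ranks
over the panel genes, so high panel expression across the board yields a
high score and predicts response to checkpoint blockade.  Ranking absorbs
any per-gene monotone normalization, so the score needs no assumptions about
the expression unit.  The AUC is computed through the tie-aware
Mann-Whitney identity and cross-checked internally against the trapezoidal
area of the threshold-sweep ROC curve — the two agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSet, validate_metadata
from .panels import PanelDefinition

logger = logging.getLogger(__name__)


@dataclass
class RankScoreTable:
    """Per-sample sum of across-cohort ranks over ``genes_used`` genes.

    With G genes over S samples each raw score lies in [G, G*S].  If
    ``rescaled`` the sum is divided by G*S, mapping it to (0, 1] for
    cross-cohort comparability.
    """

    scores: pd.Series
    genes_used: int
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.scores = self.scores.rename("sum_of_ranks")


@dataclass
class RocResult:
    """ROC points (FPR, TPR) from (0,0) to (1,1) plus the tie-aware AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def rank_samples_per_gene(
    matrix: ExpressionMatrix, genes: list[str]
) -> pd.DataFrame:
    """Across-cohort sample ranks for each requested gene (rows = genes).

    Ranks ascend with expression (lowest sample = 1), ties averaged.
    Requested genes absent from the matrix are dropped with a warning.
    """
    if matrix.n_samples < 2:
        raise ValidationError("ranking needs >= 2 samples")
    present = [g for g in genes if g in matrix.data.index]
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        logger.warning(
            "rank_samples_per_gene: %d requested gene(s) absent, using %d: "
            "missing %s",
            len(missing),
            len(present),
            missing,
        )
    if not present:
        raise ValidationError(f"none of the requested genes present: {genes}")
    sub = matrix.data.loc[present]
    ranks = np.apply_along_axis(
        lambda row: rankdata(row, method="average"), 1, sub.to_numpy(dtype=float)
    )
    return pd.DataFrame(ranks, index=present, columns=matrix.sample_ids)


def sum_of_ranks(
    per_gene_ranks: pd.DataFrame, rescale_by_genes: bool = False
) -> RankScoreTable:
    """Sum each sample's ranks across the available genes."""
    if per_gene_ranks.shape[0] < 1:
        raise ValidationError("sum_of_ranks needs ranks from >= 1 gene")
    sums = per_gene_ranks.sum(axis=0)
    g, s = per_gene_ranks.shape
    if rescale_by_genes:
        sums = sums / (g * s)
    sums.index.name = "sample_id"
    return RankScoreTable(scores=sums, genes_used=g, rescaled=rescale_by_genes)


def _as_binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    mapping = {"responder": True, "non-responder": False}
    unknown = set(labels) - set(mapping)
    if unknown:
        raise ValidationError(
            f"labels must be responder/non-responder or bool, got {sorted(unknown)}"
        )
    return np.asarray([mapping[x] for x in labels])


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for a real-valued score against binary response.

    AUC equals the probability a random responder outscores a random
    non-responder, ties counted half (Mann-Whitney identity); it is asserted
    to coincide with the trapezoidal area under the threshold-sweep curve.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_binary_labels(labels)
    if scores.shape != pos.shape:
        raise ValidationError("scores and labels must align")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"both classes required: {n_pos} responders, {n_neg} non-responders"
        )
    # threshold sweep over unique score values, descending
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    distinct = np.flatnonzero(
        np.concatenate((sorted_scores[1:] != sorted_scores[:-1], [True]))
    )
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    tpr = np.concatenate(([0.0], tps / n_pos))
    fpr = np.concatenate(([0.0], fps / n_neg))
    thresholds = np.concatenate(([np.inf], sorted_scores[distinct]))
    auc_trapezoid = float(np.trapezoid(tpr, fpr))
    # tie-aware Mann-Whitney identity
    r = rankdata(scores, method="average")
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc_u = float(u / (n_pos * n_neg))
    assert abs(auc_trapezoid - auc_u) < 1e-12, (auc_trapezoid, auc_u)
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_u, n_pos=n_pos, n_neg=n_neg
    )


@dataclass
class PredictionResult:
    """Sum-of-ranks evaluation of a gene set on an on-treatment cohort."""

    scores: RankScoreTable
    pooled: RocResult
    per_arm: dict[str, RocResult] = field(default_factory=dict)


@dataclass
class CohortPrediction:
    panel: PredictionResult
    control: PredictionResult | None = None


def _evaluate_gene_set(
    matrix: ExpressionMatrix,
    genes: list[str],
    meta: pd.DataFrame,
    ranking: str,
    rescale_by_genes: bool,
) -> PredictionResult:
    meta = meta.set_index("sample_id").loc[matrix.sample_ids]
    if ranking == "pooled":
        table = sum_of_ranks(
            rank_samples_per_gene(matrix, genes), rescale_by_genes
        )
        scores = table.scores
    elif ranking == "per_arm":
        # cohort-relative ranks within each arm; rescale so arms of unequal
        # size remain comparable when pooled
        pieces = []
        genes_used = None
        for arm, arm_meta in meta.groupby("arm"):
            sub = matrix.subset_samples(arm_meta.index.tolist())
            t = sum_of_ranks(rank_samples_per_gene(sub, genes), rescale_by_genes=True)
            genes_used = t.genes_used
            pieces.append(t.scores)
        scores = pd.concat(pieces).loc[matrix.sample_ids]
        table = RankScoreTable(scores=scores, genes_used=genes_used, rescaled=True)
    else:
        raise ValueError(f"unknown ranking mode {ranking!r}")
    labels = meta["response"]
    pooled = roc_auc(scores.to_numpy(), labels.to_numpy())
    per_arm = {}
    for arm, arm_meta in meta.groupby("arm"):
        arm_labels = arm_meta["response"]
        if arm_labels.nunique() < 2:
            logger.warning("arm %r has a single response class; AUC skipped", arm)
            continue
        per_arm[str(arm)] = roc_auc(
            scores.loc[arm_meta.index].to_numpy(), arm_labels.to_numpy()
        )
    return PredictionResult(scores=table, pooled=pooled, per_arm=per_arm)


def predict_cohort(
    matrix: ExpressionMatrix,
    panel: PanelDefinition,
    meta: pd.DataFrame,
    controls: GeneSet | None = None,
    ranking: str = "pooled",
    rescale_by_genes: bool = False,
) -> CohortPrediction:
    """Sum-of-ranks prediction on an on-treatment cohort, panel vs controls.

    Samples must carry responder/non-responder labels; ranking is
    cohort-relative ("pooled" ranks across all arms together, the default;
    "per_arm" ranks within each treatment arm separately).  A matching
    control-set evaluation is produced when ``controls`` is supplied.
    """
    meta = validate_metadata(meta)
    unmatched = set(matrix.sample_ids) - set(meta["sample_id"])
    if unmatched:
        raise ValidationError(f"samples without metadata: {sorted(unmatched)}")
    meta = meta[meta["sample_id"].isin(matrix.sample_ids)]
    on_treatment = meta[meta["response"].isin(["responder", "non-responder"])]
    if on_treatment["response"].nunique() < 2:
        raise ValidationError("cohort needs both responders and non-responders")
    sub = matrix.subset_samples(on_treatment["sample_id"].tolist())
    panel_result = _evaluate_gene_set(
        sub, list(panel.immunogenicity_genes), on_treatment, ranking, rescale_by_genes
    )
    logger.info(
        "predict_cohort: panel pooled AUC %.3f over %d genes",
        panel_result.pooled.auc,
        panel_result.scores.genes_used,
    )
    control_result = None
    if controls is not None:
        control_result = _evaluate_gene_set(
            sub, sorted(controls.genes), on_treatment, ranking, rescale_by_genes
        )
    return CohortPrediction(panel=panel_result, control=control_result)
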