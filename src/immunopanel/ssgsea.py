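"""Single-sample gene-set enrichment (ssGSEA), ESTIMATE-style.

For one sample, genes are ranked by expression within that sample (rank 1 =
lowest, rank N = highest, ties averaged).  Walking down the ranking from the
highest-expressed gene, two cumulative fractions are tracked: P_in, the
rank-weighted fraction of the gene set encountered so far (weights r^alpha),
and P_out, the fraction of out-of-set genes encountered so far.  The
enrichment score is the sum of (P_in - P_out) over all N positions — large
and positive when the set concentrates at the top of the sample's ranking.

Tie dialect: positions that share a tied rank all carry the cumulative
values at the end of their tie block (a threshold sweep over distinct
expression values).  On tie-free data this is exactly the classic positional
walk; with all genes tied the score is exactly 0, and the result never
depends on how tied genes are ordered.  The walk order itself breaks rank
ties by gene symbol so any exported running-sum curve is reproducible.

Scores are per-sample by construction: no cross-sample normalization is
applied unless ``rescale_range`` is set, which divides each set's scores by
their range across samples (a dialect some ssGSEA implementations use).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSet

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SsgseaParams:
    """ssGSEA tuning knobs.

    alpha
        Non-negative exponent weighting ranks in P_in; 0.25 matches the
        ESTIMATE implementation.  alpha = 0 gives the unweighted
        Kolmogorov-Smirnov-style running sum.
    rescale_range
        Divide each set's scores by their max-min range across samples
        (off by default; per-sample scores are the primary dialect).
    """

    alpha: float = 0.25
    rescale_range: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")


def rank_within_sample(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Ranks in [1, N] ascending with expression; ties get average ranks."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("rank_within_sample needs a 1-D vector of >= 2 genes")
    return rankdata(values, method="average")


def _prepare_sample(values: np.ndarray, gene_ids: np.ndarray):
    """Rank one sample and order genes for the enrichment walk."""
    ranks = rank_within_sample(values)
    # primary key: decreasing rank; tie-break: gene symbol (deterministic)
    order = np.lexsort((gene_ids, -ranks))
    r_ord = ranks[order]
    # index of the last position of each tied-rank block, per position
    is_block_end = np.empty(len(r_ord), dtype=bool)
    is_block_end[-1] = True
    is_block_end[:-1] = r_ord[1:] != r_ord[:-1]
    ends = np.flatnonzero(is_block_end)
    reps = np.diff(np.concatenate(([-1], ends)))
    block_end_idx = np.repeat(ends, reps)
    return ranks, order, block_end_idx


def _es_from_prepared(
    ranks: np.ndarray,
    order: np.ndarray,
    block_end_idx: np.ndarray,
    in_set: np.ndarray,
    alpha: float,
) -> float:
    n_total = len(ranks)
    n_in = int(in_set.sum())
    mask = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(mask, w, 0.0)
    p_in = np.cumsum(w_in)
    p_in /= p_in[-1]
    p_out = np.cumsum(~mask) / (n_total - n_in)
    diff = p_in[block_end_idx] - p_out[block_end_idx]
    return float(diff.sum())


def ssgsea_score(
    values: pd.Series, gene_set: GeneSet, params: SsgseaParams | None = None
) -> float:
    """Enrichment score of ``gene_set`` in one sample.

    ``values`` is a per-gene expression Series indexed by gene symbol.
    Set genes absent from the universe are dropped with a warning; an empty
    effective set, or a set covering the whole universe, is an error.
    """
    params = params or SsgseaParams()
    gene_ids = values.index.to_numpy(dtype=object)
    present = gene_set.genes & set(gene_ids)
    dropped = gene_set.genes - present
    if dropped:
        logger.warning(
            "ssgsea_score: %d gene(s) of set %r absent from universe: %s",
            len(dropped),
            gene_set.name,
            sorted(dropped),
        )
    if not present:
        raise ValidationError(
            f"no gene of set {gene_set.name!r} is present in the universe"
        )
    if len(present) == len(gene_ids):
        raise ValidationError(
            f"set {gene_set.name!r} covers the whole universe; "
            "the out-of-set walk is undefined"
        )
    ranks, order, block_end_idx = _prepare_sample(
        values.to_numpy(dtype=float), gene_ids
    )
    in_set = np.isin(gene_ids, sorted(present))
    return _es_from_prepared(ranks, order, block_end_idx, in_set, params.alpha)


def score_matrix(
    matrix: ExpressionMatrix,
    gene_sets: Sequence[GeneSet],
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Enrichment score per (sample, set); one column per set.

    Each sample is scored independently — permuting or subsetting samples
    never changes another sample's score.
    """
    params = params or SsgseaParams()
    gene_ids = np.asarray(matrix.gene_ids, dtype=object)
    universe = set(matrix.gene_ids)
    masks = {}
    for gs in gene_sets:
        present = gs.genes & universe
        dropped = gs.genes - present
        if dropped:
            logger.warning(
                "score_matrix: set %r: %d gene(s) absent from universe: %s",
                gs.name,
                len(dropped),
                sorted(dropped),
            )
        if not present:
            raise ValidationError(f"set {gs.name!r} has no gene in the universe")
        if len(present) == len(gene_ids):
            raise ValidationError(f"set {gs.name!r} covers the whole universe")
        if gs.name in masks:
            raise ValidationError(f"duplicate set name {gs.name!r}")
        masks[gs.name] = np.isin(gene_ids, sorted(present))

    values = matrix.data.to_numpy(dtype=float)
    out = np.empty((matrix.n_samples, len(masks)))
    for j in range(matrix.n_samples):
        try:
            ranks, order, block_end_idx = _prepare_sample(values[:, j], gene_ids)
            for k, mask in enumerate(masks.values()):
                out[j, k] = _es_from_prepared(
                    ranks, order, block_end_idx, mask, params.alpha
                )
        except ValidationError as exc:
            raise ValidationError(
                f"sample {matrix.sample_ids[j]!r}: {exc}"
            ) from exc
    table = pd.DataFrame(out, index=matrix.sample_ids, columns=list(masks))
    table.index.name = "sample_id"
    if params.rescale_range:
        rng = table.max(axis=0) - table.min(axis=0)
        rng = rng.replace(0.0, 1.0)
        table = table / rng
    return table
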