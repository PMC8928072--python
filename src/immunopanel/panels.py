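"""The 15-gene immune activation/checkpoint panel and its named scores.

The panel is fixed a priori: 6 immune-activation genes (the IFN-gamma /
T-cell chemotaxis / cytotoxicity axis) and 9 checkpoint-pathway genes (the
PD-1 and CTLA-4 axes plus LAG3, HAVCR2, BTLA).  The activation, checkpoint
and immunogenicity scores are the ssGSEA enrichment of the 6-gene, 9-gene
and full 15-gene sets respectively.  A 15-gene non-immune control set ships
alongside as the negative-control signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSet, read_gmt
from .ssgsea import SsgseaParams, score_matrix

logger = logging.getLogger(__name__)

ACTIVATION_GENES = ("IFNG", "CXCL9", "CXCL10", "CD8A", "PRF1", "GZMB")
CHECKPOINT_GENES = (
    "PDCD1",
    "CD274",
    "PDCD1LG2",
    "CTLA4",
    "CD80",
    "CD86",
    "LAG3",
    "HAVCR2",
    "BTLA",
)
#: shipped non-immune control signature (15 randomly chosen non-immune genes)
CONTROL_GENES = (
    "AMIGO1",
    "CDH1",
    "CYCS",
    "EFNA3",
    "EFNA5",
    "EPHA7",
    "NFKBIE",
    "NKIRAS1",
    "P4HA2",
    "S100A5",
    "S1PR2",
    "SDHA",
    "SEMA3F",
    "SEMA4B",
    "SEMA5A",
)


@dataclass(frozen=True)
class PanelDefinition:
    """Activation + checkpoint gene panel, with an optional control set.

    Invariants: activation and checkpoint sets are disjoint; the
    immunogenicity set is their union (15 genes for the default panel).
    """

    activation_genes: tuple[str, ...] = ACTIVATION_GENES
    checkpoint_genes: tuple[str, ...] = CHECKPOINT_GENES
    control_genes: tuple[str, ...] | None = CONTROL_GENES

    def __post_init__(self) -> None:
        act, chk = set(self.activation_genes), set(self.checkpoint_genes)
        if len(act) != len(self.activation_genes) or len(chk) != len(
            self.checkpoint_genes
        ):
            raise ValidationError("panel gene lists contain duplicates")
        if act & chk:
            raise ValidationError(
                f"activation and checkpoint sets overlap: {sorted(act & chk)}"
            )
        if not act or not chk:
            raise ValidationError("panel needs >= 1 activation and >= 1 checkpoint gene")

    @property
    def immunogenicity_genes(self) -> tuple[str, ...]:
        return tuple(self.activation_genes) + tuple(self.checkpoint_genes)

    @property
    def activation_set(self) -> GeneSet:
        return GeneSet("activation", frozenset(self.activation_genes))

    @property
    def checkpoint_set(self) -> GeneSet:
        return GeneSet("checkpoint", frozenset(self.checkpoint_genes))

    @property
    def immunogenicity_set(self) -> GeneSet:
        return GeneSet("immunogenicity", frozenset(self.immunogenicity_genes))

    @property
    def control_set(self) -> GeneSet | None:
        if self.control_genes is None:
            return None
        return GeneSet("control", frozenset(self.control_genes))


def default_panel() -> PanelDefinition:
    """The shipped 6 + 9 gene panel with the shipped 15-gene control set."""
    return PanelDefinition()


def load_panel_gmt() -> list[GeneSet]:
    """The shipped panel as GMT gene sets (activation, checkpoint, immunogenicity)."""
    with resources.as_file(
        resources.files("immunopanel.data").joinpath("panel.gmt")
    ) as p:
        return read_gmt(p)


def load_controls_gmt() -> GeneSet:
    """The shipped 15-gene non-immune control set."""
    with resources.as_file(
        resources.files("immunopanel.data").joinpath("controls.gmt")
    ) as p:
        return read_gmt(p)[0]


def compute_panel_scores(
    matrix: ExpressionMatrix,
    panel: PanelDefinition | None = None,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Per-sample activation, checkpoint and immunogenicity ssGSEA scores.

    Panel genes absent from the matrix (e.g. a platform lacking BTLA) are
    dropped with a warning; scoring proceeds on the genes present.  At least
    one activation and one checkpoint gene must be present.
    """
    panel = panel or default_panel()
    universe = set(matrix.gene_ids)
    act = [g for g in panel.activation_genes if g in universe]
    chk = [g for g in panel.checkpoint_genes if g in universe]
    missing = set(panel.immunogenicity_genes) - universe
    if missing:
        logger.warning(
            "compute_panel_scores: %d panel gene(s) absent from matrix, "
            "scoring on %d genes: missing %s",
            len(missing),
            len(act) + len(chk),
            sorted(missing),
        )
    if not act or not chk:
        raise ValidationError(
            "panel scoring needs >= 1 activation and >= 1 checkpoint gene "
            f"present; found {len(act)} activation, {len(chk)} checkpoint"
        )
    sets = [
        GeneSet("activation", frozenset(act)),
        GeneSet("checkpoint", frozenset(chk)),
        GeneSet("immunogenicity", frozenset(act + chk)),
    ]
    return score_matrix(matrix, sets, params)


def compute_control_scores(
    matrix: ExpressionMatrix,
    control_set: GeneSet | None = None,
    params: SsgseaParams | None = None,
) -> pd.Series:
    """ssGSEA score of the control signature, per sample."""
    control_set = control_set or load_controls_gmt()
    present = control_set.genes & set(matrix.gene_ids)
    if not present:
        raise ValidationError("no control gene present in matrix")
    table = score_matrix(
        matrix, [GeneSet(control_set.name, frozenset(present))], params
    )
    return table[control_set.name]


def draw_control_panel(
    universe: list[str],
    n: int,
    excluded: set[str],
    seed: int,
) -> GeneSet:
    """Uniformly sample ``n`` genes without replacement from the non-excluded
    universe; reproducible for a fixed seed."""
    eligible = sorted(set(universe) - set(excluded))
    if len(eligible) < n:
        raise ValidationError(
            f"only {len(eligible)} eligible genes for a control panel of {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False)
    return GeneSet(
        name=f"random_control_n{n}_seed{seed}",
        genes=frozenset(chosen.tolist()),
        description="randomly drawn non-immune control panel",
    )
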