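"""Text-format IO: expression matrices (TSV), gene sets (GMT), cohort metadata.

Expression matrices are tab-separated, genes as rows (first column holds the
gene symbol), samples as columns (first row holds the sample identifiers).
Values are non-negative, finite, linear-scale expression in arbitrary units;
all downstream scoring is rank-based and therefore unit-insensitive.

Gene identifiers are HGNC-style symbols, matched case-sensitively after
whitespace trimming.  A small shipped alias table maps common protein names
(PD-1, PD-L1, TIM-3, ...) onto gene symbols (PDCD1, CD274, HAVCR2, ...) at
load time, because panel definitions are often written with protein names
while expression matrices carry gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: metadata columns and their admissible values (None = free-form / numeric)
CONDITIONS = ("tumor", "normal")
ARMS = ("anti-PD-1", "anti-CTLA-4", "none")
RESPONSES = ("responder", "non-responder", "not-applicable")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    Invariants: at least one gene, no duplicate symbols (enforced by the
    set container), non-empty name.
    """

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("GeneSet name must be non-empty")
        if len(self.genes) == 0:
            raise ValidationError(f"GeneSet {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    ``data`` is a pandas DataFrame with unique gene symbols as the index and
    unique sample identifiers as the columns.  All values must be finite and
    non-negative; at least 2 genes and 1 sample are required.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene rows: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample columns: {dup}")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValidationError(
                f"matrix must have >= 2 genes and >= 1 sample, got {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid expression value {values[g, s]!r} for gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r} "
                "(values must be finite and >= 0)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[list(samples)])


# ---------------------------------------------------------------------------
# gene-symbol aliases


def load_alias_table() -> dict[str, str]:
    """Return the shipped protein-name -> gene-symbol alias map."""
    text = (
        resources.files("immunopanel.data").joinpath("gene_aliases.tsv").read_text()
    )
    aliases: dict[str, str] = {}
    for i, line in enumerate(text.splitlines()):
        if i == 0 or not line.strip():
            continue
        alias, symbol = line.split("\t")
        aliases[alias.strip()] = symbol.strip()
    return aliases


_ALIASES = load_alias_table()


def resolve_symbols(names: Iterable[str]) -> list[str]:
    """Trim whitespace and map known protein-name aliases to gene symbols."""
    return [_ALIASES.get(n.strip(), n.strip()) for n in names]


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, aliases: bool = True) -> ExpressionMatrix:
    """Read a genes-by-samples TSV into a validated :class:`ExpressionMatrix`.

    First row: sample ids; first column: gene symbols.  Duplicate gene rows
    are rejected naming the gene; negative or missing values are rejected
    naming gene and sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed expression matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (expected TSV)")
    df.index = pd.Index(resolve_symbols(df.index.astype(str)), name="gene")
    df.columns = [str(c).strip() for c in df.columns]
    if df.isna().to_numpy().any():
        col = df.columns[df.isna().any(axis=0)][0]
        gene = df.index[df[col].isna()][0]
        raise ValidationError(
            f"{path}: missing value for gene {gene!r}, sample {col!r}"
        )
    try:
        return ExpressionMatrix(df.astype(float))
    except (ValidationError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g"
) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


def intersect_universe(
    matrices: Sequence[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene universe.

    Gene ordering follows the first matrix; per-matrix samples are untouched.
    Mirrors restricting two cohorts to their shared protein-coding genes
    before enrichment scoring.
    """
    if len(matrices) < 2:
        raise ValidationError("intersect_universe needs >= 2 matrices")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError("gene universes have an empty intersection")
    ordered = [g for g in matrices[0].gene_ids if g in common]
    logger.info("intersect_universe: %d genes in common", len(ordered))
    return [m.subset_genes(ordered) for m in matrices]


def merge_sample_tables(
    matrices: Sequence[ExpressionMatrix], keep: str = "first"
) -> ExpressionMatrix:
    """Concatenate cohort tables sample-wise over the common gene universe.

    A sample present in more than one table is kept from the earliest table
    only (the convention used when a patient appears in two published
    supplementary tables).
    """
    if keep != "first":
        raise ValueError("only keep='first' is supported")
    if len(matrices) == 1:
        return matrices[0]
    restricted = intersect_universe(matrices)
    seen: set[str] = set()
    cols = []
    for m in restricted:
        for s in m.sample_ids:
            if s in seen:
                logger.warning(
                    "merge_sample_tables: duplicate sample %r ignored "
                    "(first occurrence kept)",
                    s,
                )
                continue
            seen.add(s)
            cols.append(m.data[s])
    return ExpressionMatrix(pd.concat(cols, axis=1))


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, aliases: bool = True) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, description, *genes = fields
        genes = [g for g in genes if g.strip()]
        if aliases:
            genes = resolve_symbols(genes)
        unique = frozenset(genes)
        if len(unique) < len(genes):
            logger.warning(
                "%s:%d: %d duplicate gene(s) collapsed in set %r",
                path,
                lineno,
                len(genes) - len(unique),
                name,
            )
        sets.append(GeneSet(name=name, genes=unique, description=description))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cohort metadata

METADATA_COLUMNS = (
    "sample_id",
    "tissue",
    "condition",
    "arm",
    "response",
    "pathology_score",
    "true_infiltration",
)


def validate_metadata(
    meta: pd.DataFrame, matrix: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Validate a per-sample metadata table.

    Required columns: sample_id, condition.  Optional: tissue, arm, response,
    pathology_score (ordinal 0-3 or missing), true_infiltration (synthetic
    cohorts only).  ``response`` may differ from "not-applicable" only for
    samples on a treatment arm.
    """
    meta = meta.copy()
    if "sample_id" not in meta.columns or "condition" not in meta.columns:
        raise ValidationError("metadata needs 'sample_id' and 'condition' columns")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate metadata rows for samples: {dup}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition values: {sorted(bad)}")
    if "arm" not in meta.columns:
        meta["arm"] = "none"
    if "response" not in meta.columns:
        meta["response"] = "not-applicable"
    bad = set(meta["arm"]) - set(ARMS)
    if bad:
        raise ValidationError(f"unknown arm values: {sorted(bad)}")
    bad = set(meta["response"]) - set(RESPONSES)
    if bad:
        raise ValidationError(f"unknown response values: {sorted(bad)}")
    off_arm = (meta["arm"] == "none") & (meta["response"] != "not-applicable")
    if off_arm.any():
        raise ValidationError(
            "response label set for samples with no treatment arm: "
            f"{meta.loc[off_arm, 'sample_id'].tolist()}"
        )
    if "pathology_score" in meta.columns:
        vals = meta["pathology_score"].dropna()
        if len(vals) and not vals.isin([0, 1, 2, 3]).all():
            raise ValidationError("pathology_score must be ordinal 0-3 or missing")
    if matrix is not None:
        missing = set(matrix.sample_ids) - set(meta["sample_id"])
        if missing:
            raise ValidationError(
                f"matrix samples without metadata: {sorted(missing)}"
            )
    return meta


def read_metadata(
    path: str | Path, matrix: ExpressionMatrix | None = None
) -> pd.DataFrame:
    try:
        meta = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed metadata table: {exc}") from exc
    return validate_metadata(meta, matrix)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
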