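"""Expression-matrix and rules-table I/O plus the normalization chain.

Bulk expression matrices arrive as delimited text with genes in rows and
samples in columns.  The normalization chain mirrors standard practice for
rank-based classification on RNA-seq: convert RPKM or raw counts to TPM,
restrict to protein-coding genes, and log2-transform.  Because the
downstream classifier depends only on within-sample gene orderings, every
step here is strictly monotone within a sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "ExpressionValidationError",
    "read_expression_matrix",
    "rpkm_to_tpm",
    "counts_to_tpm",
    "log2_normalize",
    "filter_protein_coding",
    "read_rules_table",
    "write_rules_table",
    "rules_table_from_models",
    "models_from_rules_table",
]

VALID_SCALES = ("rpkm", "counts", "tpm", "log2tpm")
TPM_TOTAL = 1e6
RULES_COLUMNS = ["drug", "rank", "gene_a", "gene_b", "direction"]
RULE_DIRECTION = "a_gt_b_votes_sensitive"


class ExpressionValidationError(ValueError):
    """Raised when an expression matrix or rules table violates its contract."""


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric expression table with a scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = gene ids, columns = sample ids.
    scale : str
        One of ``rpkm``, ``counts``, ``tpm``, ``log2tpm``.  On the three
        linear scales all values must be non-negative; ``tpm`` columns
        must each sum to 1e6 (relative tolerance 1e-6).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ExpressionValidationError(
                f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}"
            )
        df = self.values
        if df.shape[0] == 0:
            raise ExpressionValidationError("no genes: expression matrix is empty")
        if df.shape[1] == 0:
            raise ExpressionValidationError("no samples: expression matrix is empty")
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ExpressionValidationError(f"duplicate gene ids: {dup_genes}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ExpressionValidationError(f"duplicate sample ids: {dup_samples}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ExpressionValidationError("expression values must be finite")
        if self.scale in ("rpkm", "counts", "tpm") and (arr < 0).any():
            raise ExpressionValidationError(
                f"negative values not allowed on scale {self.scale!r}"
            )
        if self.scale == "tpm":
            sums = arr.sum(axis=0)
            bad = np.abs(sums - TPM_TOTAL) > 1e-6 * TPM_TOTAL
            if bad.any():
                names = df.columns[bad].tolist()
                raise ExpressionValidationError(
                    f"TPM columns must sum to 1e6; offending samples: {names}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneAnnotation:
    """Protein-coding gene set and (optional) effective gene lengths.

    Lengths in base pairs are required only for the counts→TPM conversion
    and must be strictly positive.
    """

    protein_coding: set[str] = field(default_factory=set)
    gene_length: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, l in self.gene_length.items() if not l > 0]
        if bad:
            raise ExpressionValidationError(f"non-positive gene lengths for: {bad}")


def read_expression_matrix(path: str | Path, scale: str, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression matrix (first column gene ids, header samples).

    The separator is inferred from the file extension (``.csv`` → comma,
    otherwise tab) unless given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0:
        raise ExpressionValidationError(f"no genes in {path}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ExpressionValidationError(
            f"non-numeric values in columns {non_numeric} of {path}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale)


def rpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale RPKM columns to TPM: TPM_ij = RPKM_ij / Σ_i RPKM_ij × 1e6."""
    if m.scale != "rpkm":
        raise ExpressionValidationError(f"expected scale 'rpkm', got {m.scale!r}")
    sums = m.values.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ExpressionValidationError(f"all-zero expression columns: {zero}")
    tpm = m.values.div(sums, axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "tpm")


def counts_to_tpm(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene effective lengths.

    rate_ij = counts_ij / length_i, then columns rescaled to sum to 1e6.
    """
    if m.scale != "counts":
        raise ExpressionValidationError(f"expected scale 'counts', got {m.scale!r}")
    missing = [g for g in m.gene_ids if g not in ann.gene_length]
    if missing:
        raise ExpressionValidationError(f"missing gene lengths for: {missing}")
    lengths = np.array([ann.gene_length[g] for g in m.gene_ids])
    rates = m.values.div(lengths, axis=0)
    sums = rates.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ExpressionValidationError(f"all-zero expression columns: {zero}")
    tpm = rates.div(sums, axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "tpm")


def log2_normalize(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); strictly monotone, so within-sample gene order is kept."""
    if m.scale != "tpm":
        raise ExpressionValidationError(f"expected scale 'tpm', got {m.scale!r}")
    if not pseudocount > 0:
        raise ExpressionValidationError(f"pseudocount must be > 0, got {pseudocount}")
    return ExpressionMatrix(np.log2(m.values + pseudocount), "log2tpm")


def filter_protein_coding(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Keep only genes in the protein-coding annotation, preserving order."""
    keep = [g for g in m.gene_ids if g in ann.protein_coding]
    if not keep:
        raise ExpressionValidationError(
            "no protein-coding genes retained; annotation disjoint from matrix"
        )
    return ExpressionMatrix(m.values.loc[keep], m.scale)


# ---------------------------------------------------------------------------
# Rules tables (classifier gene pairs, one CSV row per rule)
# ---------------------------------------------------------------------------

def _validate_rules_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RULES_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionValidationError(f"rules table missing columns: {missing}")
    df = df[RULES_COLUMNS].copy()
    df["rank"] = df["rank"].astype(int)
    for drug, grp in df.groupby("drug"):
        ranks = sorted(grp["rank"].tolist())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ExpressionValidationError(
                f"drug {drug!r}: ranks must be 1..k with no gaps, got {ranks}"
            )
        genes = grp["gene_a"].tolist() + grp["gene_b"].tolist()
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        if dupes:
            raise ExpressionValidationError(
                f"drug {drug!r}: genes appear in more than one rule: {dupes}"
            )
        bad_dir = grp["direction"][grp["direction"] != RULE_DIRECTION].unique().tolist()
        if bad_dir:
            raise ExpressionValidationError(
                f"drug {drug!r}: unknown rule direction(s) {bad_dir}"
            )
    return df


def read_rules_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a classifier rules CSV (columns drug,rank,gene_a,gene_b,direction)."""
    df = pd.read_csv(path, dtype={"drug": str, "gene_a": str, "gene_b": str})
    return _validate_rules_table(df)


def write_rules_table(df: pd.DataFrame, path: str | Path, excel: bool = False) -> None:
    """Write a validated rules table as CSV (or XLSX when ``excel`` is set)."""
    df = _validate_rules_table(df)
    if excel or str(path).lower().endswith(".xlsx"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def rules_table_from_models(models: Mapping[str, "KTSPResults"]) -> pd.DataFrame:  # noqa: F821
    """Flatten fitted kTSP models (drug → results) into one rules table."""
    rows = []
    for drug, model in models.items():
        for rank, rule in enumerate(model.rules, start=1):
            rows.append(
                {
                    "drug": drug,
                    "rank": rank,
                    "gene_a": rule.gene_a,
                    "gene_b": rule.gene_b,
                    "direction": RULE_DIRECTION,
                }
            )
    return _validate_rules_table(pd.DataFrame(rows, columns=RULES_COLUMNS))


def models_from_rules_table(df: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    """Oriented (gene_a, gene_b) pairs per drug, in rank order."""
    df = _validate_rules_table(df)
    out: dict[str, list[tuple[str, str]]] = {}
    for drug, grp in df.groupby("drug"):
        grp = grp.sort_values("rank")
        out[str(drug)] = list(zip(grp["gene_a"], grp["gene_b"]))
    return out
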