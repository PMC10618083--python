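"""Readers and writers for the pipeline's tabular inputs and outputs.

The canonical dialect is TSV: tab-separated, UTF-8, header row, "." decimal.
Gene annotation is additionally accepted as BED (0-based half-open), which
is converted to a 1-based TSS at read time.  Readers reject rather than
coerce: every validation error names the offending row or column.  Floats
are written with 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    COHORT_BASE_COLUMNS,
    TWAS_COLUMNS,
    CohortTable,
    ColocTable,
    ExpressionMatrix,
    TwasPanel,
)
from .exceptions import FormatError, ValidationError

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc


def read_twas_table(path, tissue: str) -> TwasPanel:
    """Read one tissue's TWAS summary table.

    Rows with missing ``zscore`` or ``pvalue`` are dropped with a logged
    count; structural problems (missing columns, duplicate gene ids,
    out-of-range p-values) raise.
    """
    df = _read_tsv(path)
    missing = [c for c in TWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing TWAS column(s) {missing}")
    incomplete = df["zscore"].isna() | df["pvalue"].isna()
    if incomplete.any():
        log.warning(
            "%s: dropped %d row(s) with missing zscore/pvalue", path, int(incomplete.sum())
        )
        df = df[~incomplete]
    return TwasPanel(tissue=tissue, table=df[list(TWAS_COLUMNS)].reset_index(drop=True))


def write_twas_table(panel: TwasPanel, path) -> None:
    panel.table[list(TWAS_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_expression(path) -> ExpressionMatrix:
    """Read a samples x genes expression TSV (first column ``sample_id``)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression table has no gene columns")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got '{df.columns[0]}'")
    df = df.set_index("sample_id")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValidationError(
            f"{path}: missing expression value at sample '{row}', gene '{col}' "
            "(no imputation is performed)"
        )
    em = ExpressionMatrix(data=df.astype(float), standardized=False)
    log.info("%s: read expression matrix %d samples x %d genes", path, em.n_samples, em.n_genes)
    return em


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_cohort(path) -> CohortTable:
    """Read the per-sample phenotype/covariate/PRS table."""
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: cohort table must have a 'sample_id' column")
    missing = [c for c in COHORT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort column(s) {missing}")
    return CohortTable(data=df.set_index("sample_id"))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_coloc(path) -> ColocTable:
    df = _read_tsv(path)
    missing = [c for c in ("gene_id", "tissue", "glcp") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing colocalization column(s) {missing}")
    return ColocTable(data=df)


def write_coloc(coloc: ColocTable, path) -> None:
    coloc.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_annotation_bed(path) -> pd.DataFrame:
    """Read gene annotation from BED (chrom, start, end, gene_id).

    BED is 0-based half-open; the returned table carries a 1-based TSS
    (``start + 1``) with columns ``gene_id, chrom, tss``.
    """
    try:
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "gene_id": str},
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse as 4-column BED: {exc}") from exc
    if (bed["start"] < 0).any() or (bed["end"] <= bed["start"]).any():
        bad = bed.loc[(bed["start"] < 0) | (bed["end"] <= bed["start"]), "gene_id"]
        raise ValidationError(f"{path}: invalid BED interval(s) for {bad.tolist()[:5]}")
    if bed["gene_id"].duplicated().any():
        dup = bed.loc[bed["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValidationError(f"{path}: duplicate gene_id(s) in annotation: {dup}")
    out = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "tss": (bed["start"] + 1).astype(np.int64),
        }
    )
    return out


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """Write a ``gene_id, chrom, tss`` table as 4-column BED (0-based start)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"].astype(np.int64) - 1,
            "end": annotation["tss"].astype(np.int64),
            "gene_id": annotation["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def align_cohort(
    expr: ExpressionMatrix, cohort: CohortTable
) -> tuple[ExpressionMatrix, CohortTable]:
    """Restrict expression and cohort to their shared samples, same order.

    The output order is the expression matrix's order filtered to the
    intersection, which makes the operation idempotent.  Dropped sample
    counts are logged; an empty intersection raises.
    """
    expr_ids = expr.data.index
    cohort_ids = cohort.data.index
    common = expr_ids[expr_ids.isin(cohort_ids)]
    if len(common) == 0:
        raise ValidationError("expression and cohort share no sample_ids")
    dropped_expr = len(expr_ids) - len(common)
    dropped_cohort = len(cohort_ids) - len(common)
    if dropped_expr or dropped_cohort:
        log.info(
            "align_cohort: dropped %d expression and %d cohort sample(s) outside the intersection",
            dropped_expr,
            dropped_cohort,
        )
    expr_out = ExpressionMatrix(
        data=expr.data.loc[common], standardized=expr.standardized
    )
    cohort_out = CohortTable(data=cohort.data.loc[common])
    return expr_out, cohort_out
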