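"""Shared data model for the TRS pipeline.

All tabular objects are thin, validated wrappers around pandas DataFrames:

* :class:`TwasPanel` — one tissue's gene-level TWAS results (signed Z, p,
  genomic position); the source of score weights and selection p-values.
* :class:`ExpressionMatrix` — samples x genes observed expression.
* :class:`CohortTable` — per-sample phenotype, covariates and PRS.
* :class:`ColocTable` — per (gene, tissue) locus-level colocalization
  probabilities (GLCP).

Validation happens at construction: readers never hand out objects that
violate the invariants below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

TWAS_COLUMNS = ("gene_id", "zscore", "pvalue", "chrom", "tss")
COHORT_BASE_COLUMNS = ("phenotype", "sex", "age", "wave", "prs")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing required column(s) {missing}")


@dataclass
class TwasPanel:
    """Gene-level TWAS summary statistics for a single expression panel.

    Parameters
    ----------
    tissue
        Panel name (e.g. ``"cortex"``).
    table
        DataFrame with columns ``gene_id, zscore, pvalue, chrom, tss``.
        ``zscore`` is the signed TWAS Z used as the score weight; ``pvalue``
        must lie in (0, 1]; ``tss`` is a 1-based transcription start site.
    """

    tissue: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.table, TWAS_COLUMNS, f"TWAS panel '{self.tissue}'")
        t = self.table.reset_index(drop=True).copy()
        dup = t["gene_id"][t["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"TWAS panel '{self.tissue}': duplicate gene_id(s) "
                f"{sorted(dup.unique())[:5]}"
            )
        z = pd.to_numeric(t["zscore"], errors="coerce")
        p = pd.to_numeric(t["pvalue"], errors="coerce")
        if not np.isfinite(z).all():
            bad = t.loc[~np.isfinite(z), "gene_id"].tolist()[:5]
            raise ValidationError(
                f"TWAS panel '{self.tissue}': non-finite zscore for {bad}"
            )
        out = (p <= 0) | (p > 1) | ~np.isfinite(p)
        if out.any():
            bad = t.loc[out, "gene_id"].tolist()[:5]
            raise ValidationError(
                f"TWAS panel '{self.tissue}': pvalue outside (0, 1] for {bad}"
            )
        tss = pd.to_numeric(t["tss"], errors="coerce")
        if (~np.isfinite(tss)).any() or (tss < 0).any():
            bad = t.loc[~np.isfinite(tss) | (tss < 0), "gene_id"].tolist()[:5]
            raise ValidationError(
                f"TWAS panel '{self.tissue}': invalid tss for {bad}"
            )
        t["zscore"] = z.astype(float)
        t["pvalue"] = p.astype(float)
        t["tss"] = tss.astype(np.int64)
        t["chrom"] = t["chrom"].astype(str)
        t["gene_id"] = t["gene_id"].astype(str)
        object.__setattr__(self, "table", t)

    @property
    def n_genes_tested(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def equals(self, other: "TwasPanel") -> bool:
        return self.tissue == other.tissue and self.table[list(TWAS_COLUMNS)].equals(
            other.table[list(TWAS_COLUMNS)]
        )


@dataclass
class ExpressionMatrix:
    """Samples x genes expression, optionally standardized per gene.

    ``data`` is indexed by sample_id with one column per gene.  When
    ``standardized`` is True every gene column has mean 0 and sample
    (n-1 denominator) standard deviation 1 to within 1e-8.
    """

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0:
            raise ValidationError("expression matrix has no genes")
        if self.data.shape[0] == 0:
            raise ValidationError("expression matrix has no samples")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicated sample_id(s) in expression: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicated gene id(s) in expression: {dup}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                "expression matrix has a missing/non-finite value at "
                f"sample '{self.data.index[i]}', gene '{self.data.columns[j]}'"
            )
        if self.standardized:
            mu = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.ones(vals.shape[1])
            if np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-8:
                raise ValidationError(
                    "standardized flag set but columns are not mean-0 / sd-1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortTable:
    """Per-sample phenotype, covariates and polygenic score.

    ``data`` is indexed by sample_id and carries ``phenotype`` (strictly 0/1),
    ``sex`` and ``wave`` (categorical), ``age`` (years), ``prs`` and any
    number of genetic principal-component columns named ``PC1..PCk``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, COHORT_BASE_COLUMNS, "cohort table")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicated sample_id(s) in cohort: {dup}")
        y = pd.to_numeric(self.data["phenotype"], errors="coerce")
        if not y.isin([0, 1]).all():
            bad = self.data.index[~y.isin([0, 1])].tolist()[:5]
            raise ValidationError(
                f"phenotype must be strictly 0/1; offending sample(s): {bad}"
            )
        d = self.data.copy()
        d["phenotype"] = y.astype(int)
        d["age"] = pd.to_numeric(d["age"])
        d["prs"] = pd.to_numeric(d["prs"])
        object.__setattr__(self, "data", d)

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def phenotype(self) -> np.ndarray:
        return self.data["phenotype"].to_numpy(dtype=float)

    @property
    def prs(self) -> np.ndarray:
        return self.data["prs"].to_numpy(dtype=float)

    @property
    def pc_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith("PC") and c[2:].isdigit()]
        return sorted(cols, key=lambda c: int(c[2:]))

    @property
    def covariate_columns(self) -> list[str]:
        return ["sex", "age", "wave", *self.pc_columns]

    @property
    def n_cases(self) -> int:
        return int(self.data["phenotype"].sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.data["phenotype"]).sum())


@dataclass
class ColocTable:
    """Gene locus-level colocalization probabilities per (gene, tissue)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _require_columns(self.data, ("gene_id", "tissue", "glcp"), "colocalization table")
        d = self.data.reset_index(drop=True).copy()
        g = pd.to_numeric(d["glcp"], errors="coerce")
        bad = ~np.isfinite(g) | (g < 0) | (g > 1)
        if bad.any():
            rows = d.loc[bad, ["gene_id", "tissue"]].head(5).to_records(index=False)
            raise ValidationError(f"GLCP outside [0, 1] for {list(rows)}")
        if d.duplicated(subset=["gene_id", "tissue"]).any():
            rows = d.loc[
                d.duplicated(subset=["gene_id", "tissue"]), ["gene_id", "tissue"]
            ].head(5).to_records(index=False)
            raise ValidationError(f"duplicate (gene_id, tissue) coloc rows: {list(rows)}")
        d["glcp"] = g.astype(float)
        object.__setattr__(self, "data", d)

    def for_tissue(self, tissue: str) -> pd.Series:
        """GLCP values for one tissue, indexed by gene_id."""
        sub = self.data[self.data["tissue"] == tissue]
        return sub.set_index("gene_id")["glcp"]
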