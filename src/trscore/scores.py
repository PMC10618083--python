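"""Gene selection and transcriptomic risk score construction.

A TRS for sample *i* over a selected gene set *S* is

    TRS_i = sum_{g in S} z_g * x_ig

where ``z_g`` is the gene's signed TWAS Z-score and ``x_ig`` the sample's
standardized observed expression.  Genes enter *S* by a ladder of TWAS
p-value thresholds (per-panel Bonferroni, 0.001, 0.05, 0.1, 0.2, 0.3, 0.4,
0.5, 1).  Two restricted variants are provided: locus pruning (one lead
gene per 500 kb single-linkage locus) and colocalization filtering
(GLCP >= cutoff).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ColocTable, ExpressionMatrix, TwasPanel
from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: The p-value threshold ladder used for the per-tissue scan.
THRESHOLD_LADDER = ("BF", "0.001", "0.05", "0.1", "0.2", "0.3", "0.4", "0.5", "1")

DEFAULT_LOCUS_GAP = 500_000


@dataclass
class GeneSelection:
    """A selected signature gene set with its score weights.

    ``gene_ids`` are ordered by ascending TWAS p (ties by gene_id);
    ``weights`` are the matching signed Z-scores.  An empty selection is a
    legal, flagged result: the TRS is undefined for it and the caller
    decides how to proceed.
    """

    tissue: str
    threshold_label: str
    threshold_value: float
    gene_ids: list[str] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != len(self.weights):
            raise ValidationError("gene_ids and weights must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in selection")
        if len(self.weights) and not np.isfinite(self.weights).all():
            raise ValidationError("non-finite weight in selection")

    @property
    def is_empty(self) -> bool:
        return len(self.gene_ids) == 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class TrsProfile:
    """Per-sample TRS values for one (tissue, threshold)."""

    tissue: str
    threshold_label: str
    scores: pd.Series          # indexed by sample_id, raw weighted sum
    n_genes: int

    @property
    def standardized_scores(self) -> pd.Series:
        """Scores divided by their own sample SD (per-SD scale for regression)."""
        sd = self.scores.std(ddof=1)
        if sd == 0 or not math.isfinite(sd):
            raise ValidationError(
                f"TRS for {self.tissue}/{self.threshold_label} has zero variance"
            )
        return self.scores / sd


@dataclass
class LocusSet:
    """Partition of genes into single-linkage loci (<= gap_bp joins)."""

    gap_bp: int
    loci: list[pd.DataFrame]   # each: gene_id, chrom, tss of one cluster

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def cluster_of(self, gene_id: str) -> int:
        for k, c in enumerate(self.loci):
            if (c["gene_id"] == gene_id).any():
                return k
        raise KeyError(gene_id)


def bonferroni_threshold(panel: TwasPanel, alpha: float = 0.05) -> float:
    """Per-panel Bonferroni threshold ``alpha / n_genes_tested``."""
    if panel.n_genes_tested < 1:
        raise ValidationError(f"panel '{panel.tissue}' is empty")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    return alpha / panel.n_genes_tested


def resolve_threshold(panel: TwasPanel, threshold_label: str, alpha: float = 0.05) -> float:
    if threshold_label == "BF":
        return bonferroni_threshold(panel, alpha)
    if threshold_label not in THRESHOLD_LADDER:
        raise ValidationError(
            f"unknown threshold label '{threshold_label}'; expected one of {THRESHOLD_LADDER}"
        )
    return float(threshold_label)


def select_genes(
    panel: TwasPanel, threshold_label: str, alpha: float = 0.05
) -> GeneSelection:
    """Select the panel's genes with TWAS p <= threshold, Z as weights.

    Output order is ascending p-value with ties broken by gene_id, so the
    selection is deterministic.  An empty result is returned flagged, not
    raised.
    """
    thr = resolve_threshold(panel, threshold_label, alpha)
    hits = panel.table[panel.table["pvalue"] <= thr]
    hits = hits.sort_values(["pvalue", "gene_id"], kind="mergesort")
    return GeneSelection(
        tissue=panel.tissue,
        threshold_label=threshold_label,
        threshold_value=thr,
        gene_ids=hits["gene_id"].tolist(),
        weights=hits["zscore"].to_numpy(),
    )


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each gene column to mean 0, sample SD 1 (n-1 denominator)."""
    vals = expr.values
    if vals.shape[0] < 2:
        raise ValidationError("need at least 2 samples to standardize")
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        gene = expr.data.columns[zero][0]
        raise ValidationError(f"gene '{gene}' has zero variance; cannot standardize")
    out = pd.DataFrame(
        (vals - mu) / sd, index=expr.data.index, columns=expr.data.columns
    )
    return ExpressionMatrix(data=out, standardized=True)


def compute_trs(expr_std: ExpressionMatrix, selection: GeneSelection) -> TrsProfile:
    """Weighted sum of standardized expression over the selected genes.

    Genes selected in the TWAS but absent from the expression matrix are
    dropped with a logged count; an empty post-intersection set raises.
    """
    if not expr_std.standardized:
        raise ValidationError("expression must be standardized before scoring")
    if selection.is_empty:
        raise ValidationError(
            f"empty gene selection for {selection.tissue}/{selection.threshold_label}"
        )
    present = [g in expr_std.data.columns for g in selection.gene_ids]
    n_missing = len(present) - sum(present)
    if n_missing:
        log.info(
            "compute_trs %s/%s: %d of %d selected gene(s) absent from expression, dropped",
            selection.tissue,
            selection.threshold_label,
            n_missing,
            len(present),
        )
    genes = [g for g, ok in zip(selection.gene_ids, present) if ok]
    if not genes:
        raise ValidationError(
            f"no selected gene for {selection.tissue}/{selection.threshold_label} "
            "is present in the expression matrix"
        )
    w = selection.weights[np.asarray(present)]
    scores = expr_std.data[genes].to_numpy() @ w
    return TrsProfile(
        tissue=selection.tissue,
        threshold_label=selection.threshold_label,
        scores=pd.Series(scores, index=expr_std.data.index, name="trs"),
        n_genes=len(genes),
    )


def cluster_loci(positions: pd.DataFrame, gap_bp: int = DEFAULT_LOCUS_GAP) -> LocusSet:
    """Single-linkage locus clustering of genes within ``gap_bp``.

    ``positions`` must carry ``gene_id, chrom, tss``.  Per chromosome,
    genes are sorted by TSS and adjacent genes at distance <= gap_bp are
    chained into the same locus (boundary inclusive on the merge side; an
    exact tie at gap_bp is logged).  Loci never span chromosomes.
    """
    for col in ("gene_id", "chrom", "tss"):
        if col not in positions.columns:
            raise ValidationError(f"locus clustering needs column '{col}'")
    if positions["tss"].isna().any() or positions["chrom"].isna().any():
        bad = positions.loc[
            positions["tss"].isna() | positions["chrom"].isna(), "gene_id"
        ].tolist()[:5]
        raise ValidationError(f"missing position for gene(s) {bad}")
    loci: list[pd.DataFrame] = []
    for _, chrom_df in positions.groupby("chrom", sort=True):
        chrom_df = chrom_df.sort_values(["tss", "gene_id"], kind="mergesort")
        gaps = chrom_df["tss"].diff().to_numpy()
        if np.any(gaps[1:] == gap_bp):
            log.info("cluster_loci: adjacent genes exactly %d bp apart merged", gap_bp)
        breaks = np.flatnonzero(gaps[1:] > gap_bp) + 1
        for piece in np.split(np.arange(len(chrom_df)), breaks):
            loci.append(chrom_df.iloc[piece][["gene_id", "chrom", "tss"]].reset_index(drop=True))
    return LocusSet(gap_bp=gap_bp, loci=loci)


def selection_positions(selection: GeneSelection, panel: TwasPanel) -> pd.DataFrame:
    """Positions (``gene_id, chrom, tss``) of a selection's genes from its panel."""
    tab = panel.table.set_index("gene_id")
    missing = [g for g in selection.gene_ids if g not in tab.index]
    if missing:
        raise ValidationError(f"selection gene(s) missing from panel: {missing[:5]}")
    sub = tab.loc[selection.gene_ids, ["chrom", "tss"]].reset_index()
    return sub


def prune_to_lead(
    selection: GeneSelection, loci: LocusSet, panel: TwasPanel
) -> GeneSelection:
    """Keep one gene per locus: lowest TWAS p, ties by smaller TSS then gene_id."""
    if selection.is_empty:
        return selection
    tab = panel.table.set_index("gene_id")
    selected = set(selection.gene_ids)
    leads: list[str] = []
    for cluster in loci.loci:
        genes = [g for g in cluster["gene_id"] if g in selected]
        if not genes:
            continue
        info = tab.loc[genes, ["pvalue", "tss"]].reset_index()
        info = info.sort_values(["pvalue", "tss", "gene_id"], kind="mergesort")
        leads.append(info.iloc[0]["gene_id"])
    covered = set().union(*(set(c["gene_id"]) for c in loci.loci)) if loci.loci else set()
    uncovered = selected - covered
    if uncovered:
        raise ValidationError(
            f"loci do not cover selected gene(s): {sorted(uncovered)[:5]}"
        )
    order = {g: i for i, g in enumerate(selection.gene_ids)}
    leads.sort(key=lambda g: order[g])
    weights = {g: w for g, w in zip(selection.gene_ids, selection.weights)}
    return GeneSelection(
        tissue=selection.tissue,
        threshold_label=selection.threshold_label,
        threshold_value=selection.threshold_value,
        gene_ids=leads,
        weights=np.array([weights[g] for g in leads]),
    )


def restrict_colocalized(
    selection: GeneSelection, coloc: ColocTable, cutoff: float = 0.5
) -> GeneSelection:
    """Retain genes with GLCP >= cutoff in the selection's tissue.

    The cutoff is inclusive (a gene at exactly the cutoff is kept); genes
    with no colocalization record are dropped.  An all-removed result is
    returned flagged-empty, not raised.
    """
    if not 0 <= cutoff <= 1:
        raise ValidationError("colocalization cutoff must lie in [0, 1]")
    glcp = coloc.for_tissue(selection.tissue)
    keep = [
        (g, w)
        for g, w in zip(selection.gene_ids, selection.weights)
        if g in glcp.index and glcp[g] >= cutoff
    ]
    dropped = selection.n_genes - len(keep)
    if dropped:
        log.info(
            "restrict_colocalized %s/%s: dropped %d gene(s) below GLCP %.2f or unrecorded",
            selection.tissue,
            selection.threshold_label,
            dropped,
            cutoff,
        )
    return GeneSelection(
        tissue=selection.tissue,
        threshold_label=selection.threshold_label,
        threshold_value=selection.threshold_value,
        gene_ids=[g for g, _ in keep],
        weights=np.array([w for _, w in keep]),
    )
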