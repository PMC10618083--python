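"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route possible
(double loops, all-pairs graphs, per-cluster scans) and never call the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def trs_double_loop(values: np.ndarray, gene_index: dict, gene_ids, weights) -> np.ndarray:
    """TRS per sample by an explicit double loop over samples and genes."""
    n = values.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for g, w in zip(gene_ids, weights):
            out[i] += w * values[i, gene_index[g]]
    return out


def select_by_filter(table: pd.DataFrame, threshold: float) -> set:
    """Gene set with p <= threshold by direct per-row comparison."""
    return {row.gene_id for row in table.itertuples() if row.pvalue <= threshold}


class _DSU:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[ra] = rb


def loci_connected_components(positions: pd.DataFrame, gap_bp: int) -> set:
    """Loci as connected components of the all-pairs proximity graph.

    Edge between genes i, j iff same chromosome and |tss_i - tss_j| <= gap_bp.
    Returns a set of frozensets of gene_ids.
    """
    genes = positions["gene_id"].tolist()
    chrom = positions["chrom"].tolist()
    tss = positions["tss"].tolist()
    dsu = _DSU(len(genes))
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if chrom[i] == chrom[j] and abs(tss[i] - tss[j]) <= gap_bp:
                dsu.union(i, j)
    comps: dict[int, set] = {}
    for i, g in enumerate(genes):
        comps.setdefault(dsu.find(i), set()).add(g)
    return {frozenset(c) for c in comps.values()}


def lead_per_cluster(clusters, panel_table: pd.DataFrame) -> set:
    """Lowest-p gene per cluster; ties by smaller TSS, then gene_id."""
    info = panel_table.set_index("gene_id")
    leads = set()
    for cluster in clusters:
        best = min(
            cluster,
            key=lambda g: (info.loc[g, "pvalue"], info.loc[g, "tss"], g),
        )
        leads.add(best)
    return leads


def pearson_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / sd formula."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def random_panel(rng: np.random.Generator, n_genes: int, tissue: str = "t"):
    """A random but valid TWAS panel table (p consistent with |Z|)."""
    from scipy import stats

    z = rng.standard_normal(n_genes) * rng.uniform(0.5, 3)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    chroms = rng.choice([f"chr{c}" for c in range(1, 4)], size=n_genes)
    tss = rng.integers(1, 5_000_000, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(n_genes)],
            "zscore": z,
            "pvalue": p,
            "chrom": chroms,
            "tss": tss,
        }
    )
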