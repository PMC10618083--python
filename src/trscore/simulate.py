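"""Synthetic multi-tissue TWAS / expression / cohort generator.

Every downstream stage of the pipeline (scoring, association, permutation,
multiplicity correction) is testable against data from this module, which
emulates the statistical structure the analysis assumes:

* per-gene TWAS Z-scores equicorrelated across tissues, with signal genes
  receiving a shared mean shift of random sign;
* observed expression simulated directly on the standardized scale
  (controls ~ N(0, 1) per gene), with case expression for signal genes
  shifted in the direction of the gene's TWAS Z;
* a case-control cohort ascertained from a covariate/PRS logistic liability,
  with case and control counts fixed by design;
* colocalization probabilities drawn high for signal genes, low otherwise.

All generators are pure functions of ``(config, seed)``: each draws from its
own RNG stream seeded at ``seed + fixed offset``, so adding one generator
never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable, ColocTable, ExpressionMatrix, TwasPanel
from .exceptions import ValidationError

# RNG stream offsets per generator (pure function of config.seed + offset)
_TRUTH_OFFSET = 11
_TWAS_OFFSET = 29
_COHORT_OFFSET = 47
_COLOC_OFFSET = 83

# GLCP distributions: signal genes high-mean Beta(8, 2), others Beta(2, 8)
COLOC_CAUSAL_AB = (8.0, 2.0)
COLOC_NULL_AB = (2.0, 8.0)

#: GTEx-style panel names used for the first 14 simulated tissues.
TISSUE_NAMES = (
    "whole_blood",
    "amygdala",
    "anterior_cingulate_cortex",
    "caudate",
    "cerebellar_hemisphere",
    "cerebellum",
    "cortex",
    "frontal_cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus_accumbens",
    "putamen",
    "spinal_cord",
    "substantia_nigra",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    The cohort size (222 cases / 269 controls), number of tissues (14),
    per-panel gene count, cross-tissue Z correlation and PRS effect mirror
    the adult ADHD case-control study the pipeline reimplements; the
    per-gene expression shift default is set so the resulting score-level
    case-control difference (~0.35 SD) matches the per-SD logistic
    estimates the analysis typically reports (0.2-0.45).

    ``expr_effect`` is the standardized mean difference added to case
    expression of each signal gene, sign-matched to the gene's TWAS Z;
    ``twas_effect`` the mean |Z| of signal genes; ``covariate_effects``
    log-odds per unit for (sex, age, wave, PC1..) in the ascertainment
    liability; ``prs_effect`` log-odds per PRS standard deviation;
    ``discordant_fraction`` the fraction of signal genes whose observed
    expression shift opposes their TWAS Z sign.
    """

    n_genes: int = 8000
    n_tissues: int = 14
    n_cases: int = 222
    n_controls: int = 269
    causal_fraction: float = 0.003
    expr_effect: float = 0.06
    twas_effect: float = 5.0
    cross_tissue_corr: float = 0.98
    covariate_effects: tuple[float, ...] = (0.09, -0.02)
    prs_effect: float = 0.33
    locus_gap: int = 600_000
    seed: int = 0
    discordant_fraction: float = 0.0
    n_pcs: int = 10
    n_chromosomes: int = 22

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tissues, self.n_cases, self.n_controls) < 1:
            raise ValidationError("n_genes, n_tissues, n_cases, n_controls must be >= 1")
        if self.n_cases + self.n_controls < 20:
            raise ValidationError("need n_cases + n_controls >= 20 for downstream fits")
        if not 0 <= self.causal_fraction <= 1:
            raise ValidationError("causal_fraction must lie in [0, 1]")
        if not 0 <= self.cross_tissue_corr < 1:
            raise ValidationError("cross_tissue_corr must lie in [0, 1)")
        if self.expr_effect < 0 or self.twas_effect < 0:
            raise ValidationError("expr_effect and twas_effect must be >= 0")
        if not 0 <= self.discordant_fraction <= 1:
            raise ValidationError("discordant_fraction must lie in [0, 1]")
        if self.locus_gap <= 0:
            raise ValidationError("locus_gap must be a positive base-pair count")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedTruth:
    """Ground truth behind one simulated dataset."""

    gene_ids: list[str]
    causal_gene_ids: list[str]
    z_sign: np.ndarray            # per gene: +-1 for signal genes, 0 otherwise
    expr_delta: np.ndarray        # per gene: case-control expression shift
    liability: pd.Series | None = field(default=None)  # per selected sample

    @property
    def causal_mask(self) -> np.ndarray:
        causal = set(self.causal_gene_ids)
        return np.array([g in causal for g in self.gene_ids])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def tissue_names(n: int) -> list[str]:
    names = list(TISSUE_NAMES[:n])
    names += [f"tissue_{i + 1}" for i in range(len(names), n)]
    return names


def make_truth(config: SimulationConfig) -> SimulatedTruth:
    """Draw signal genes, their shared Z sign, and expression shift."""
    rng = np.random.default_rng(config.seed + _TRUTH_OFFSET)
    genes = _gene_ids(config.n_genes)
    n_causal = round(config.causal_fraction * config.n_genes)
    causal_idx = rng.choice(config.n_genes, size=n_causal, replace=False)
    z_sign = np.zeros(config.n_genes)
    z_sign[causal_idx] = rng.choice([-1.0, 1.0], size=n_causal)
    concord = np.ones(config.n_genes)
    if config.discordant_fraction > 0 and n_causal:
        n_disc = round(config.discordant_fraction * n_causal)
        disc = rng.choice(causal_idx, size=n_disc, replace=False)
        concord[disc] = -1.0
    expr_delta = z_sign * concord * config.expr_effect
    return SimulatedTruth(
        gene_ids=genes,
        causal_gene_ids=[genes[i] for i in sorted(causal_idx)],
        z_sign=z_sign,
        expr_delta=expr_delta,
    )


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay genes on chromosomes with consecutive TSS spacing ``locus_gap``.

    Genes are split into near-equal consecutive blocks over
    ``n_chromosomes`` chromosomes; positions are deterministic given the
    config.  Returns a ``gene_id, chrom, tss`` table (1-based TSS).
    """
    genes = _gene_ids(config.n_genes)
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil division
    chroms, tss = [], []
    for i in range(config.n_genes):
        c, k = divmod(i, per_chrom)
        chroms.append(f"chr{c + 1}")
        tss.append(1_000_000 + k * config.locus_gap)
    return pd.DataFrame({"gene_id": genes, "chrom": chroms, "tss": np.array(tss, dtype=np.int64)})


def simulate_twas_panels(
    config: SimulationConfig, truth: SimulatedTruth
) -> list[TwasPanel]:
    """Draw per-tissue TWAS Z-scores and p-values.

    Per gene, tissue Z-scores follow an equicorrelated multivariate normal
    (pairwise correlation ``cross_tissue_corr``); signal genes receive a
    shared mean shift ``z_sign * twas_effect``.  ``p = 2 * Phi(-|Z|)``.
    """
    rng = np.random.default_rng(config.seed + _TWAS_OFFSET)
    rho = config.cross_tissue_corr
    n_g, n_t = config.n_genes, config.n_tissues
    shared = rng.standard_normal((n_g, 1))
    eps = rng.standard_normal((n_g, n_t))
    z = truth.z_sign[:, None] * config.twas_effect + np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    annotation = simulate_annotation(config).set_index("gene_id")
    panels = []
    for t, tissue in enumerate(tissue_names(n_t)):
        table = pd.DataFrame(
            {
                "gene_id": truth.gene_ids,
                "zscore": z[:, t],
                "pvalue": pvals[:, t],
                "chrom": annotation.loc[truth.gene_ids, "chrom"].to_numpy(),
                "tss": annotation.loc[truth.gene_ids, "tss"].to_numpy(),
            }
        )
        panels.append(TwasPanel(tissue=tissue, table=table))
    return panels


def simulate_cohort(
    config: SimulationConfig, truth: SimulatedTruth
) -> tuple[ExpressionMatrix, CohortTable]:
    """Simulate the ascertained case-control cohort and its expression.

    Covariates and PRS are drawn for a population pool; cases are sampled
    from the pool with weight ``exp(eta)`` where ``eta`` is the logistic
    liability from ``covariate_effects`` and ``prs_effect`` (retrospective
    sampling), controls uniformly from the remainder, and counts are fixed
    by design.  Expression is standard normal in controls; case expression
    of signal genes is shifted by the truth's signed delta.  PRS enters
    expression generation nowhere, so TRS and PRS are conditionally
    independent given case status.
    """
    rng = np.random.default_rng(config.seed + _COHORT_OFFSET)
    n = config.n_cases + config.n_controls
    pool_n = 4 * n

    sex = (rng.random(pool_n) < 0.58).astype(float)      # 1 = male
    age = rng.normal(35.0, 11.0, size=pool_n)
    wave = (rng.random(pool_n) < 0.33).astype(int)       # two genotyping waves
    pcs = rng.standard_normal((pool_n, config.n_pcs))
    prs = rng.standard_normal(pool_n)

    cov_matrix = np.column_stack([sex, age - age.mean(), wave.astype(float), pcs])
    betas = np.zeros(cov_matrix.shape[1])
    eff = np.asarray(config.covariate_effects, dtype=float)
    betas[: min(len(eff), len(betas))] = eff[: len(betas)]
    eta = cov_matrix @ betas + config.prs_effect * prs

    # Efraimidis-Spirakis weighted sampling without replacement (Gumbel keys)
    keys = eta + rng.gumbel(size=pool_n)
    case_idx = np.argsort(keys)[::-1][: config.n_cases]
    rest = np.setdiff1d(np.arange(pool_n), case_idx)
    control_idx = rng.choice(rest, size=config.n_controls, replace=False)

    chosen = np.concatenate([case_idx, control_idx])
    phenotype = np.concatenate(
        [np.ones(config.n_cases), np.zeros(config.n_controls)]
    )
    order = rng.permutation(n)
    chosen, phenotype = chosen[order], phenotype[order]

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    cohort_df = pd.DataFrame(
        {
            "phenotype": phenotype.astype(int),
            "sex": np.where(sex[chosen] > 0, "male", "female"),
            "age": age[chosen],
            "wave": np.where(wave[chosen] > 0, "wave2", "wave1"),
            "prs": prs[chosen],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for j in range(config.n_pcs):
        cohort_df[f"PC{j + 1}"] = pcs[chosen, j]

    expr = rng.standard_normal((n, config.n_genes))
    expr[phenotype == 1] += truth.expr_delta[None, :]
    expr_df = pd.DataFrame(
        expr, index=pd.Index(sample_ids, name="sample_id"), columns=truth.gene_ids
    )

    truth.liability = pd.Series(eta[chosen], index=sample_ids, name="liability")
    return ExpressionMatrix(data=expr_df), CohortTable(data=cohort_df)


def simulate_coloc(config: SimulationConfig, truth: SimulatedTruth) -> ColocTable:
    """Draw GLCP per (gene, tissue): Beta(8,2) for signal genes, Beta(2,8) otherwise."""
    rng = np.random.default_rng(config.seed + _COLOC_OFFSET)
    causal = truth.causal_mask
    n_g, n_t = config.n_genes, config.n_tissues
    a = np.where(causal, COLOC_CAUSAL_AB[0], COLOC_NULL_AB[0])
    b = np.where(causal, COLOC_CAUSAL_AB[1], COLOC_NULL_AB[1])
    glcp = rng.beta(np.repeat(a, n_t), np.repeat(b, n_t))
    df = pd.DataFrame(
        {
            "gene_id": np.repeat(truth.gene_ids, n_t),
            "tissue": np.tile(tissue_names(n_t), n_g),
            "glcp": glcp,
        }
    )
    return ColocTable(data=df)


def simulate_bundle(config: SimulationConfig):
    """Generate the full input bundle for one synthetic study.

    Returns ``(truth, annotation, panels, expression, cohort, coloc)``.
    """
    truth = make_truth(config)
    annotation = simulate_annotation(config)
    panels = simulate_twas_panels(config, truth)
    expr, cohort = simulate_cohort(config, truth)
    coloc = simulate_coloc(config, truth)
    return truth, annotation, panels, expr, cohort, coloc
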