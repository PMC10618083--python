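"""End-to-end orchestration: from input tables to the study summary table.

``run_study`` reproduces the analysis flow of the TRS study: standardize
expression, scan the threshold ladder per tissue, compute permutation
empirical p-values for the best threshold, liability-scale pseudo-R^2
increments (population prevalence 5% by default), the PRS and PRS+TRS
models with their likelihood-ratio comparison, and finally the Galwey/Sidak
multiplicity correction across tissues.  The output table is the
machine-readable twin of the study's per-tissue results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    ScanResult,
    best_threshold_scan,
    cox_snell_r2,
    covariate_design,
    empirical_pvalue,
    fit_logistic,
    lee_liability_r2,
    lrt_compare,
    quintile_odds_ratios,
    trs_prs_correlation,
)
from .datatypes import CohortTable, ColocTable, ExpressionMatrix, TwasPanel
from .exceptions import ValidationError
from .io import align_cohort
from .multiplicity import MeffResult, galwey_meff, trs_correlation_matrix
from .scores import (
    THRESHOLD_LADDER,
    cluster_loci,
    prune_to_lead,
    restrict_colocalized,
    selection_positions,
    standardize,
)

log = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "tissue",
    "n_genes",
    "best_threshold",
    "estimate",
    "pvalue",
    "empirical_pvalue",
    "pseudo_r2",
    "combined_prs_estimate",
    "combined_prs_pvalue",
    "combined_trs_estimate",
    "combined_trs_pvalue",
    "combined_pseudo_r2",
    "lrt_pvalue",
    "significant",
]


@dataclass
class StudyResult:
    """Full output of one pipeline run."""

    table: pd.DataFrame                 # one row per tissue (Table-1 shaped)
    meff: MeffResult | None
    scans: dict[str, ScanResult]
    prs_fit_summary: dict
    trs_prs_corr: pd.DataFrame
    prevalence: float
    B: int
    per_threshold: pd.DataFrame = field(default_factory=pd.DataFrame)


def _per_sd(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValidationError("score has zero variance")
    return x / sd


def _liability_increment(y, extra: pd.DataFrame, covariates: pd.DataFrame, K: float) -> float:
    """Lee-transformed Cox-Snell increment of `extra` columns over covariates."""
    P = float(np.mean(y))
    full = fit_logistic(y, covariates=pd.concat([extra, covariates], axis=1))
    cov = fit_logistic(y, covariates=covariates)
    base = fit_logistic(y)
    r2_full = lee_liability_r2(cox_snell_r2(full, base), K, P).r2_liab
    r2_cov = lee_liability_r2(cox_snell_r2(cov, base), K, P).r2_liab
    return r2_full - r2_cov


def _selection_transform(panel: TwasPanel, prune: bool, locus_gap: int,
                         coloc: ColocTable | None, coloc_cutoff: float):
    if not prune and coloc is None:
        return None

    def transform(sel):
        if coloc is not None:
            sel = restrict_colocalized(sel, coloc, coloc_cutoff)
            if sel.is_empty:
                return sel
        if prune:
            loci = cluster_loci(selection_positions(sel, panel), locus_gap)
            sel = prune_to_lead(sel, loci, panel)
        return sel

    return transform


def run_tissue(
    panel: TwasPanel,
    expr_std: ExpressionMatrix,
    cohort: CohortTable,
    covariates: pd.DataFrame,
    thresholds=THRESHOLD_LADDER,
    B: int = 10_000,
    prevalence: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
    transform=None,
) -> tuple[dict, ScanResult]:
    """One tissue's full analysis row: scan, empirical p, R^2, PRS models."""
    y = cohort.phenotype
    scan = best_threshold_scan(
        panel, expr_std, cohort, thresholds, alpha, covariates, transform
    )
    emp = empirical_pvalue(
        panel, expr_std, cohort, thresholds, B=B, seed=seed, alpha=alpha,
        covariates=covariates, transform=transform, _scan=scan,
    )
    trs = scan.best_profile.standardized_scores.to_numpy()
    trs_col = pd.DataFrame({"trs": trs})
    r2_trs = _liability_increment(y, trs_col, covariates, prevalence)

    prs = _per_sd(cohort.prs)
    both = pd.DataFrame({"prs": prs, "trs": trs})
    combined = fit_logistic(y, covariates=pd.concat([both, covariates], axis=1))
    prs_only = fit_logistic(y, score=prs, covariates=covariates, score_name="prs")
    r2_combined = _liability_increment(y, both, covariates, prevalence)
    lrt_stat, lrt_df, lrt_p = lrt_compare(prs_only, combined)

    row = {
        "tissue": panel.tissue,
        "n_genes": scan.best.n_genes,
        "best_threshold": scan.best.best_threshold_label,
        "estimate": scan.best.estimate,
        "pvalue": scan.best.pvalue,
        "empirical_pvalue": emp,
        "pseudo_r2": r2_trs,
        "combined_prs_estimate": float(combined.params["prs"]),
        "combined_prs_pvalue": float(combined.pvalues["prs"]),
        "combined_trs_estimate": float(combined.params["trs"]),
        "combined_trs_pvalue": float(combined.pvalues["trs"]),
        "combined_pseudo_r2": r2_combined,
        "lrt_pvalue": lrt_p,
    }
    scan.best.empirical_pvalue = emp
    scan.best.pseudo_r2 = r2_trs
    scan.best.B = B
    return row, scan


def run_study(
    panels: list[TwasPanel],
    expr: ExpressionMatrix,
    cohort: CohortTable,
    thresholds=THRESHOLD_LADDER,
    B: int = 10_000,
    prevalence: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
    covariate_columns: list[str] | None = None,
    prune: bool = False,
    locus_gap: int = 500_000,
    coloc: ColocTable | None = None,
    coloc_cutoff: float = 0.5,
) -> StudyResult:
    """Run the full multi-tissue TRS analysis and multiplicity correction."""
    if not panels:
        raise ValidationError("no TWAS panels supplied")
    expr, cohort = align_cohort(expr, cohort)
    expr_std = expr if expr.standardized else standardize(expr)
    covariates = covariate_design(cohort, covariate_columns).reset_index(drop=True)
    y = cohort.phenotype

    child_seeds = np.random.SeedSequence(seed).generate_state(len(panels)) % (2**31)
    rows, scans, per_threshold = [], {}, []
    for panel, child in zip(panels, child_seeds):
        transform = _selection_transform(panel, prune, locus_gap, coloc, coloc_cutoff)
        try:
            row, scan = run_tissue(
                panel, expr_std, cohort, covariates, thresholds,
                B=B, prevalence=prevalence, seed=int(child), alpha=alpha,
                transform=transform,
            )
        except ValidationError as exc:
            log.warning("tissue '%s' skipped: %s", panel.tissue, exc)
            continue
        rows.append(row)
        scans[panel.tissue] = scan
        pt = scan.rows.copy()
        pt.insert(0, "tissue", panel.tissue)
        per_threshold.append(pt)
    if not rows:
        raise ValidationError("no tissue produced a scoreable TRS")
    table = pd.DataFrame(rows)

    meff = None
    if len(scans) >= 2:
        trs_map = {t: s.best_profile.scores for t, s in scans.items()}
        meff = galwey_meff(trs_correlation_matrix(trs_map), alpha=alpha)
        table["significant"] = table["empirical_pvalue"] < meff.sidak_threshold
    else:
        table["significant"] = table["empirical_pvalue"] < alpha
    table = table[TABLE_COLUMNS]

    prs = _per_sd(cohort.prs)
    prs_fit = fit_logistic(y, score=prs, covariates=covariates, score_name="prs")
    prs_r2 = _liability_increment(y, pd.DataFrame({"prs": prs}), covariates, prevalence)
    prs_summary = {
        "estimate": prs_fit.estimate,
        "pvalue": prs_fit.score_pvalue,
        "pseudo_r2": prs_r2,
    }

    trs_map_std = {
        t: s.best_profile.standardized_scores for t, s in scans.items()
    }
    corr = trs_prs_correlation(trs_map_std, cohort.prs)

    return StudyResult(
        table=table,
        meff=meff,
        scans=scans,
        prs_fit_summary=prs_summary,
        trs_prs_corr=corr,
        prevalence=prevalence,
        B=B,
        per_threshold=pd.concat(per_threshold, ignore_index=True),
    )


def quintile_table(result: StudyResult, cohort: CohortTable,
                   covariate_columns: list[str] | None = None,
                   tissues: list[str] | None = None) -> pd.DataFrame:
    """Quintile OR profiles (Q1 baseline) for the PRS and selected TRSs."""
    _, cohort_aligned = _realign(result, cohort)
    covariates = covariate_design(cohort_aligned, covariate_columns).reset_index(drop=True)
    y = cohort_aligned.phenotype
    rows = []

    def add(name, score):
        q = quintile_odds_ratios(score, y, covariates)
        for k in range(2, 6):
            rows.append(
                {
                    "score": name,
                    "quintile": f"Q{k}",
                    "odds_ratio": float(q.odds_ratios[f"Q{k}"]),
                    "ci_low": float(q.ci_low[f"Q{k}"]),
                    "ci_high": float(q.ci_high[f"Q{k}"]),
                }
            )

    add("PRS", cohort_aligned.prs)
    wanted = tissues if tissues is not None else list(result.scans)
    for t in wanted:
        add(f"TRS:{t}", result.scans[t].best_profile.scores.to_numpy())
    return pd.DataFrame(rows)


def _realign(result: StudyResult, cohort: CohortTable):
    any_scan = next(iter(result.scans.values()))
    ids = any_scan.best_profile.scores.index
    return None, CohortTable(data=cohort.data.loc[ids])


def variance_table(result: StudyResult) -> pd.DataFrame:
    """Variance-explained decomposition: TRS, PRS and combined per tissue."""
    rows = []
    for _, r in result.table.iterrows():
        rows.append(
            {
                "tissue": r["tissue"],
                "trs_pseudo_r2": r["pseudo_r2"],
                "prs_pseudo_r2": result.prs_fit_summary["pseudo_r2"],
                "combined_pseudo_r2": r["combined_pseudo_r2"],
                "lrt_pvalue": r["lrt_pvalue"],
            }
        )
    return pd.DataFrame(rows)
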