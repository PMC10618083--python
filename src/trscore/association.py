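"""Covariate-adjusted association testing for transcriptomic and polygenic scores.

The model throughout is a logistic regression of case/control status on a
score plus covariates (sex, age, genotyping wave, genetic PCs), fitted by
iteratively reweighted least squares (Newton scoring, tolerance 1e-8, at
most 100 iterations).  On top of the fit this module provides:

* Cox-Snell pseudo-R^2 and Lee et al.'s liability-scale transformation for
  an ascertained case-control sample with population prevalence K;
* the best-p-value-threshold scan over the TRS ladder and its permutation
  empirical p-value, in which the *entire* scan is repeated on each
  permuted phenotype so the minimum is compared against its own null;
* quintile odds-ratio profiles, Pearson TRS-PRS correlation, and the
  likelihood-ratio comparison of PRS vs PRS+TRS models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import CohortTable, ExpressionMatrix, TwasPanel
from .exceptions import ConvergenceError, SeparationError, ValidationError
from .scores import THRESHOLD_LADDER, GeneSelection, TrsProfile, compute_trs, select_genes

log = logging.getLogger(__name__)

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
_BETA_DIVERGENCE = 50.0  # |beta| beyond this in a standardized design => separation


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def covariate_design(cohort: CohortTable, covariates: list[str] | None = None) -> pd.DataFrame:
    """Numeric design columns for the requested covariates.

    Categorical columns (``sex``, ``wave`` or any non-numeric column) are
    dummy-encoded with the first level as reference; numeric columns pass
    through.  No intercept column is added here.
    """
    if covariates is None:
        covariates = cohort.covariate_columns
    missing = [c for c in covariates if c not in cohort.data.columns]
    if missing:
        raise ValidationError(f"cohort table lacks covariate column(s) {missing}")
    sub = cohort.data[covariates]
    out = pd.get_dummies(sub, drop_first=True, dtype=float)
    return out.astype(float)


def _assemble_design(
    y: np.ndarray,
    score: np.ndarray | pd.Series | None,
    covariates: pd.DataFrame | None,
    score_name: str,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("phenotype must be strictly 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both phenotype classes must be present for a fit")
    cols: list[np.ndarray] = [np.ones_like(y)]
    names = ["intercept"]
    if score is not None:
        s = np.asarray(score, dtype=float).ravel()
        if len(s) != len(y):
            raise ValidationError("score and phenotype lengths differ")
        cols.append(s)
        names.append(score_name)
    if covariates is not None and covariates.shape[1]:
        if len(covariates) != len(y):
            raise ValidationError("covariate rows and phenotype length differ")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValidationError("design matrix contains non-finite values")
    return X, names, y


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in piv[diag < tol]] or [names[j] for j in piv[rank:]]
        raise ValidationError(f"design is rank deficient; collinear column(s): {bad}")


# ---------------------------------------------------------------------------
# logistic fitting (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic regression fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    converged: bool
    score_name: str | None = None

    @property
    def score_pvalue(self) -> float:
        if self.score_name is None:
            raise ValidationError("fit has no score term")
        return float(self.pvalues[self.score_name])

    @property
    def estimate(self) -> float:
        if self.score_name is None:
            raise ValidationError("fit has no score term")
        return float(self.params[self.score_name])


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = IRLS_TOL, max_iter: int = IRLS_MAX_ITER):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - p)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix during IRLS (separation or collinearity)"
            ) from exc
        beta = beta + delta
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            raise SeparationError(
                "coefficients diverged during IRLS: perfect or quasi separation"
            )
        if np.abs(delta).max() < tol:
            H = (X * np.maximum(expit(X @ beta) * (1 - expit(X @ beta)), 1e-12)[:, None]).T @ X
            return beta, H, True
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def fit_logistic(
    y,
    score=None,
    covariates: pd.DataFrame | None = None,
    score_name: str = "score",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of y on (score, covariates).

    Raises :class:`SeparationError` on perfect/quasi separation and
    :class:`ValidationError` (naming the collinear columns) on a rank
    deficient design.  The Wald two-sided p-value of the score coefficient
    is available as ``fit.score_pvalue``.
    """
    X, names, yv = _assemble_design(y, score, covariates, score_name)
    _check_rank(X, names)
    beta, H, converged = _irls(X, yv)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(zstat))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pv, index=names),
        llf=_loglik(yv, X @ beta),
        n=len(yv),
        converged=converged,
        score_name=score_name if score is not None else None,
    )


def _batch_score_wald_p(X: np.ndarray, Y: np.ndarray, score_col: int = 1) -> np.ndarray:
    """Wald two-sided p for ``X[:, score_col]`` across many phenotypes at once.

    ``Y`` is (n, B): one permuted phenotype per column.  Same Newton
    iteration as :func:`_irls`, batched over columns; permutations whose
    fit degenerates get p = NaN.
    """
    n, k = X.shape
    B = Y.shape[1]
    beta = np.zeros((B, k))
    ok = np.ones(B, dtype=bool)
    eye = np.eye(k) * 1e-12
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta.T                      # (n, B)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = np.einsum("ni,nb,nj->bij", X, w, X) + eye
        g = np.einsum("ni,nb->bi", X, Y - p)
        try:
            delta = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for b in range(B):
                try:
                    delta_b = np.linalg.solve(H[b], g[b])
                except np.linalg.LinAlgError:
                    ok[b] = False
                    delta_b = 0.0
                beta[b] += delta_b
            continue
        beta += delta
        diverged = np.abs(beta).max(axis=1) > _BETA_DIVERGENCE
        if diverged.any():
            ok &= ~diverged
            beta[diverged] = 0.0
        if np.abs(delta[ok]).max(initial=0.0) < IRLS_TOL:
            break
    eta = X @ beta.T
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-12)
    H = np.einsum("ni,nb,nj->bij", X, w, X) + np.eye(k) * 1e-12
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(cov[:, score_col, score_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, score_col] / se
    out = 2.0 * stats.norm.sf(np.abs(z))
    out[~ok] = np.nan
    return out


# ---------------------------------------------------------------------------
# pseudo-R^2 on the liability scale
# ---------------------------------------------------------------------------

def cox_snell_r2(fit_full: LogisticFit, fit_null: LogisticFit) -> float:
    """Cox-Snell R^2 = 1 - exp((2/n) (l_null - l_full)) for nested fits."""
    if fit_full.n != fit_null.n:
        raise ValidationError("fits must be on the same samples (n differs)")
    if fit_full.llf < fit_null.llf - 1e-8:
        raise ValidationError(
            "full-model log-likelihood below null's; models are not nested MLEs"
        )
    return float(1.0 - np.exp((2.0 / fit_full.n) * (fit_null.llf - fit_full.llf)))


@dataclass
class LiabilityParams:
    """Lee et al. liability-scale conversion of an observed-scale R^2.

    ``K`` is the population prevalence, ``P`` the sample case proportion,
    ``t`` the liability threshold, ``z`` the normal density at ``t``,
    ``m = z/K`` the mean liability of cases, ``C`` and ``theta`` the
    ascertainment scaling and curvature terms.
    """

    K: float
    P: float
    t: float
    z: float
    m: float
    C: float
    theta: float
    r2_cs: float
    r2_liab: float


def lee_liability_r2(r2_cs: float, K: float, P: float) -> LiabilityParams:
    """Convert a Cox-Snell R^2 to the liability scale (prevalence K).

    Implements the full ascertainment correction:
    ``t = Phi^-1(1-K)``, ``z = phi(t)``, ``m = z/K``,
    ``C = K(1-K)/z^2 * K(1-K)/(P(1-P))``,
    ``theta = m ((P-K)/(1-K)) (m (P-K)/(1-K) - t)``,
    ``R^2_liab = C R^2_CS / (1 + C theta R^2_CS)``.
    With K = P the curvature term vanishes and the transform is linear.
    """
    if not 0 <= r2_cs < 1:
        raise ValidationError("r2_cs must lie in [0, 1)")
    if not (0 < K < 1 and 0 < P < 1):
        raise ValidationError("K and P must lie in (0, 1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    m = z / K
    C = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    a = m * (P - K) / (1 - K)
    theta = a * (a - t)
    r2_liab = C * r2_cs / (1 + C * theta * r2_cs)
    return LiabilityParams(K=K, P=P, t=t, z=z, m=m, C=C, theta=theta, r2_cs=r2_cs, r2_liab=r2_liab)


def score_increment_r2(
    y,
    score,
    covariates: pd.DataFrame | None,
    K: float = 0.05,
    method: str = "transform-then-subtract",
) -> float:
    """Liability-scale pseudo-R^2 increment attributable to the score.

    ``method="transform-then-subtract"`` (default): Lee-transform the
    full-model and covariate-only Cox-Snell R^2 (each anchored at the
    intercept-only model) and subtract.  ``method="relative"``: Cox-Snell
    computed directly between the full and covariate-only fits, then
    Lee-transformed.  ``P`` is the observed case proportion.
    """
    yv = np.asarray(y, dtype=float).ravel()
    P = float(yv.mean())
    fit_full = fit_logistic(yv, score=score, covariates=covariates)
    fit_cov = fit_logistic(yv, score=None, covariates=covariates)
    if method == "relative":
        return lee_liability_r2(cox_snell_r2(fit_full, fit_cov), K, P).r2_liab
    if method != "transform-then-subtract":
        raise ValidationError(f"unknown increment method '{method}'")
    fit0 = fit_logistic(yv, score=None, covariates=None)
    r2_full = lee_liability_r2(cox_snell_r2(fit_full, fit0), K, P).r2_liab
    r2_cov = lee_liability_r2(cox_snell_r2(fit_cov, fit0), K, P).r2_liab
    return r2_full - r2_cov


# ---------------------------------------------------------------------------
# threshold scan and permutation empirical p-value
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Best-threshold association summary for one tissue's TRS (or a PRS)."""

    tissue: str
    best_threshold_label: str
    n_genes: int
    estimate: float
    pvalue: float
    empirical_pvalue: float = float("nan")
    pseudo_r2: float = float("nan")
    B: int = 0


@dataclass
class ScanResult:
    """Per-threshold fits for one tissue plus the best row."""

    tissue: str
    rows: pd.DataFrame                      # threshold_label, threshold_value, n_genes, estimate, pvalue
    best: AssociationResult
    profiles: dict[str, TrsProfile] = field(default_factory=dict)
    selections: dict[str, GeneSelection] = field(default_factory=dict)

    @property
    def best_profile(self) -> TrsProfile:
        return self.profiles[self.best.best_threshold_label]

    @property
    def best_selection(self) -> GeneSelection:
        return self.selections[self.best.best_threshold_label]


def build_profiles(
    panel: TwasPanel,
    expr_std: ExpressionMatrix,
    thresholds=THRESHOLD_LADDER,
    alpha: float = 0.05,
    transform=None,
) -> tuple[dict[str, GeneSelection], dict[str, TrsProfile]]:
    """Selections and TRS profiles for every non-empty threshold of the ladder.

    ``transform``, if given, maps each GeneSelection to a restricted one
    (locus pruning, colocalization filtering) before scoring.
    """
    selections: dict[str, GeneSelection] = {}
    profiles: dict[str, TrsProfile] = {}
    for label in thresholds:
        sel = select_genes(panel, label, alpha)
        if transform is not None and not sel.is_empty:
            sel = transform(sel)
        if sel.is_empty:
            continue
        try:
            prof = compute_trs(expr_std, sel)
        except ValidationError:
            continue
        if prof.scores.std(ddof=1) == 0:
            continue
        selections[label] = sel
        profiles[label] = prof
    return selections, profiles


def best_threshold_scan(
    panel: TwasPanel,
    expr_std: ExpressionMatrix,
    cohort: CohortTable,
    thresholds=THRESHOLD_LADDER,
    alpha: float = 0.05,
    covariates: pd.DataFrame | None = None,
    transform=None,
) -> ScanResult:
    """Fit the TRS association at every threshold; best = minimum Wald p.

    Ties are broken in favour of fewer genes.  TRS values are divided by
    their own sample SD before regression so estimates are per-SD log-odds.
    Thresholds with empty selections are skipped; all-empty raises.
    """
    if covariates is None:
        covariates = covariate_design(cohort)
    selections, profiles = build_profiles(panel, expr_std, thresholds, alpha, transform)
    if not profiles:
        raise ValidationError(
            f"no threshold in {list(thresholds)} yields a scoreable gene set for "
            f"panel '{panel.tissue}'"
        )
    y = cohort.phenotype
    records = []
    for label, prof in profiles.items():
        fit = fit_logistic(y, score=prof.standardized_scores.to_numpy(), covariates=covariates)
        records.append(
            {
                "threshold_label": label,
                "threshold_value": selections[label].threshold_value,
                "n_genes": prof.n_genes,
                "estimate": fit.estimate,
                "pvalue": fit.score_pvalue,
            }
        )
    rows = pd.DataFrame.from_records(records)
    ordered = rows.sort_values(["pvalue", "n_genes"], kind="mergesort")
    top = ordered.iloc[0]
    best = AssociationResult(
        tissue=panel.tissue,
        best_threshold_label=str(top["threshold_label"]),
        n_genes=int(top["n_genes"]),
        estimate=float(top["estimate"]),
        pvalue=float(top["pvalue"]),
    )
    return ScanResult(tissue=panel.tissue, rows=rows, best=best,
                      profiles=profiles, selections=selections)


def empirical_from_minima(observed_min: float, perm_minima: np.ndarray) -> float:
    """Permutation empirical p: (r+1)/(B+1), r = #{perm minima <= observed}."""
    perm_minima = np.asarray(perm_minima, dtype=float)
    B = len(perm_minima)
    if B < 1:
        raise ValidationError("need at least one permutation")
    r = int(np.sum(perm_minima <= observed_min))
    return (r + 1) / (B + 1)


def empirical_pvalue(
    panel: TwasPanel,
    expr_std: ExpressionMatrix,
    cohort: CohortTable,
    thresholds=THRESHOLD_LADDER,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    covariates: pd.DataFrame | None = None,
    scan_per_permutation: bool = True,
    transform=None,
    _scan: ScanResult | None = None,
) -> float:
    """Permutation empirical p-value for the best-threshold TRS association.

    The phenotype is permuted ``B`` times (covariates stay attached to their
    samples) and, by default, the *full* threshold scan is repeated on each
    permutation; the observed minimum score p-value is ranked against the
    permuted minima, so the result is free of the inflation introduced by
    picking the best threshold.  ``scan_per_permutation=False`` re-tests
    only the observed best threshold (cheaper, anti-conservative).
    """
    if B < 1:
        raise ValidationError("need at least one permutation (B >= 1)")
    if B < 99:
        log.warning("B=%d permutations is small; empirical p floor is %.3g", B, 1 / (B + 1))
    if covariates is None:
        covariates = covariate_design(cohort)
    scan = _scan or best_threshold_scan(
        panel, expr_std, cohort, thresholds, alpha, covariates, transform
    )
    y = cohort.phenotype
    rng = np.random.default_rng(seed)
    Y = np.empty((len(y), B))
    for b in range(B):
        Y[:, b] = y[rng.permutation(len(y))]
    labels = (
        list(scan.profiles)
        if scan_per_permutation
        else [scan.best.best_threshold_label]
    )
    cov_arr = covariates.to_numpy(dtype=float) if covariates is not None else None
    perm_min = np.full(B, np.inf)
    for label in labels:
        s = scan.profiles[label].standardized_scores.to_numpy()
        cols = [np.ones(len(y)), s]
        if cov_arr is not None and cov_arr.size:
            cols.append(cov_arr)
        X = np.column_stack(cols)
        p = _batch_score_wald_p(X, Y, score_col=1)
        perm_min = np.fmin(perm_min, p)
    observed = (
        scan.best.pvalue
        if scan_per_permutation
        else float(scan.rows.set_index("threshold_label").loc[scan.best.best_threshold_label, "pvalue"])
    )
    return empirical_from_minima(observed, perm_min)


# ---------------------------------------------------------------------------
# quintiles, correlations, model comparison
# ---------------------------------------------------------------------------

@dataclass
class QuintileResult:
    """Odds ratios of score quintiles Q2-Q5 vs the first quintile."""

    odds_ratios: pd.Series       # index Q2..Q5
    ci_low: pd.Series
    ci_high: pd.Series
    counts: pd.Series            # samples per quintile, index Q1..Q5


def quintile_bins(n: int, n_bins: int = 5) -> np.ndarray:
    """Bin sizes for an equal-count split; the remainder goes to lower bins."""
    base, rem = divmod(n, n_bins)
    return np.array([base + (1 if i < rem else 0) for i in range(n_bins)])


def quintile_odds_ratios(
    score, y, covariates: pd.DataFrame | None = None
) -> QuintileResult:
    """Logistic ORs (Wald 95% CI) for score quintiles, Q1 as baseline."""
    s = np.asarray(score, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    n = len(s)
    if n < 50:
        raise ValidationError("quintile analysis needs n >= 50")
    sizes = quintile_bins(n)
    order = np.argsort(s, kind="mergesort")
    q = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes):
        q[order[start : start + size]] = k + 1
        start += size
    for k in range(1, 6):
        classes = np.unique(yv[q == k])
        if len(classes) < 2:
            raise ValidationError(f"quintile Q{k} contains a single phenotype class")
    dummies = pd.DataFrame(
        {f"Q{k}": (q == k).astype(float) for k in range(2, 6)}
    )
    if covariates is not None:
        dummies = pd.concat([dummies, covariates.reset_index(drop=True)], axis=1)
    fit = fit_logistic(yv, score=None, covariates=dummies)
    idx = [f"Q{k}" for k in range(2, 6)]
    beta = fit.params[idx]
    se = fit.bse[idx]
    zcrit = stats.norm.isf(0.025)
    return QuintileResult(
        odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - zcrit * se),
        ci_high=np.exp(beta + zcrit * se),
        counts=pd.Series(sizes, index=[f"Q{k}" for k in range(1, 6)]),
    )


def trs_prs_correlation(trs_map: dict[str, "pd.Series | np.ndarray"], prs) -> pd.DataFrame:
    """Pearson r (two-sided p, Bonferroni across pairs) between TRSs and a PRS."""
    prs_v = np.asarray(prs, dtype=float).ravel()
    if len(prs_v) < 3:
        raise ValidationError("need at least 3 samples for a correlation")
    if np.std(prs_v) == 0:
        raise ValidationError("PRS vector has zero variance")
    records = []
    for name, trs in trs_map.items():
        t = np.asarray(trs, dtype=float).ravel()
        if len(t) != len(prs_v):
            raise ValidationError(f"TRS '{name}' length differs from PRS")
        if np.std(t) == 0:
            raise ValidationError(f"TRS '{name}' has zero variance")
        r, p = stats.pearsonr(t, prs_v)
        records.append({"trs": name, "r": float(r), "pvalue": float(p)})
    out = pd.DataFrame.from_records(records)
    out["pvalue_bonferroni"] = np.minimum(out["pvalue"] * len(out), 1.0)
    return out


def lrt_compare(fit_null: LogisticFit, fit_full: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic fits: (statistic, df, p)."""
    if fit_null.n != fit_full.n:
        raise ValidationError("LRT requires fits on identical samples (n differs)")
    if not set(fit_null.params.index) <= set(fit_full.params.index):
        raise ValidationError("models are not nested (null has terms absent from full)")
    df = len(fit_full.params) - len(fit_null.params)
    stat = 2.0 * (fit_full.llf - fit_null.llf)
    if stat < -1e-6:
        raise ValidationError("full model fits worse than null; models are not nested MLEs")
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0 if stat < 1e-8 else 0.0
    return stat, df, float(stats.chi2.sf(stat, df))
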