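"""Effective number of independent tests and the Sidak-corrected threshold.

Best-threshold TRSs from different tissues are strongly correlated, so a
plain Bonferroni correction over tissues is too strict.  Galwey's estimator
replaces the test count m with

    Meff = (sum_j sqrt(lambda_j))^2 / sum_j lambda_j

over the (negative-clamped) eigenvalues of the TRS Pearson correlation
matrix, and the family-wise level alpha is converted to a per-test
threshold by the Sidak formula 1 - (1 - alpha)^(1/Meff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class MeffResult:
    """Eigenvalue-based effective test count and derived Sidak threshold."""

    corr: np.ndarray
    eigenvalues: np.ndarray     # descending, negative values clamped to 0
    meff_raw: float
    meff: int
    alpha: float
    sidak_threshold: float
    labels: list[str] | None = None


def sidak_threshold(alpha: float, meff: int) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/meff)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if meff < 1:
        raise ValidationError("meff must be >= 1")
    return float(1.0 - (1.0 - alpha) ** (1.0 / meff))


def galwey_meff(corr, alpha: float = 0.05) -> MeffResult:
    """Galwey effective number of tests from a correlation matrix.

    Eigenvalues are clamped at zero (empirical correlation matrices of
    nearly collinear scores can dip slightly negative), ``meff_raw`` is the
    Galwey ratio, and ``meff`` its half-away-from-zero rounding clamped to
    ``[1, m]``.
    """
    labels = None
    if isinstance(corr, pd.DataFrame):
        labels = [str(c) for c in corr.columns]
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1] or corr.shape[0] < 1:
        raise ValidationError("correlation matrix must be square and non-empty")
    m = corr.shape[0]
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValidationError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have a unit diagonal")
    lam = np.linalg.eigvalsh(corr)[::-1]
    lam = np.clip(lam, 0.0, None)
    meff_raw = float(np.sum(np.sqrt(lam)) ** 2 / np.sum(lam))
    meff = int(np.clip(np.floor(meff_raw + 0.5), 1, m))
    return MeffResult(
        corr=corr,
        eigenvalues=lam,
        meff_raw=meff_raw,
        meff=meff,
        alpha=alpha,
        sidak_threshold=sidak_threshold(alpha, meff),
        labels=labels,
    )


def trs_correlation_matrix(trs_map: dict[str, "pd.Series | np.ndarray"]) -> pd.DataFrame:
    """Pearson correlation matrix of best-threshold TRSs across tissues.

    Scores must be complete (no missing values) and sample-aligned; a
    zero-variance score raises.
    """
    df = pd.DataFrame({k: np.asarray(v, dtype=float).ravel() for k, v in trs_map.items()})
    if df.isna().any().any():
        raise ValidationError("TRS matrix has missing values; pairwise-complete "
                              "correlation is not supported")
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValidationError(f"zero-variance TRS: {sd.index[sd == 0].tolist()}")
    return df.corr(method="pearson")
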