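"""Covariate-adjusted partial Pearson correlations with cognition.

A partial correlation between x and y given covariates Z is the Pearson
correlation of the residuals of x and y after least-squares regression on
[1, Z].  Significance uses t = r * sqrt(df / (1 - r^2)) with
df = n - k - 2 for k covariates.  Here the covariates are baseline age,
sex, education band, and APOE e4 allele count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LongitudinalCohort
from .labels import CANONICAL_NAMES
from .volumetrics import ChangeTable, DegenerateInputError, aggregate_volumes, percent_change


@dataclass
class AssociationResult:
    label: str
    r: float
    p_value: float
    n: int
    df: int

    @property
    def star(self) -> str:
        """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def n_covariates(Z) -> int:
    """Number of covariate columns in Z (0 for None/empty; 1-D counts as one)."""
    if Z is None:
        return 0
    Z = np.asarray(Z)
    if Z.size == 0:
        return 0
    return 1 if Z.ndim == 1 else Z.shape[1]


def _design(Z: np.ndarray | None, n: int) -> np.ndarray:
    if Z is None:
        return np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.size and Z.shape[0] != n:
        raise ValueError("covariate matrix row count does not match n")
    D = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate design matrix (with intercept) is rank-deficient")
    return D


def residualize(X: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of X after least squares on [1, Z]."""
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    X = X.reshape(X.shape[0], -1)
    D = _design(Z, X.shape[0])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    R = X - D @ beta
    return R.ravel() if one_d else R


def partial_correlation(x, y, Z=None) -> tuple[float, float]:
    """Partial Pearson r of x and y given covariates Z, and two-sided p.

    With Z empty this reduces to the plain Pearson correlation
    (df = n - 2).  Requires n > k + 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    k = n_covariates(Z)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    R = residualize(np.column_stack([x, y]), Z)
    sd = R.std(axis=0)
    # relative floor: numerically-zero residuals mean x (or y) is constant or
    # fully explained by the covariates
    floor = 1e-10 * np.maximum(np.column_stack([x, y]).std(axis=0), 1e-30)
    if np.any(sd <= floor):
        which = "x" if sd[0] <= floor[0] else "y"
        raise DegenerateInputError(f"(near-)zero-variance residuals for {which}")
    r = float(np.corrcoef(R[:, 0], R[:, 1])[0, 1])
    r = min(1.0, max(-1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return r, float(p)


def associate_cognition(
    changes: ChangeTable,
    covariates: np.ndarray,
    cohort: LongitudinalCohort | None = None,
    include_aggregates: bool = False,
) -> list[AssociationResult]:
    """Partial correlation of each subfield's volume change with MMSE decline.

    ``include_aggregates`` appends whole-hippocampus / whole-head / whole-body
    rows whose changes are computed from summed volumes (requires ``cohort``).
    """
    y = changes.cognitive_decline_pct
    n = changes.n_subjects
    df = n - n_covariates(covariates) - 2
    results = []
    for j, name in enumerate(CANONICAL_NAMES):
        r, p = partial_correlation(changes.volume_change_pct[:, j], y, covariates)
        results.append(AssociationResult(label=name, r=r, p_value=p, n=n, df=df))
    if include_aggregates:
        if cohort is None:
            raise ValueError("aggregates require the cohort for summed volumes")
        for name, (base, follow) in aggregate_volumes(cohort).items():
            x = percent_change(base, follow, context=name)
            r, p = partial_correlation(x, y, covariates)
            results.append(AssociationResult(label=name, r=r, p_value=p, n=n, df=df))
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Report table: label, r, p, star."""
    return pd.DataFrame(
        {
            "label": [a.label for a in results],
            "r": [a.r for a in results],
            "p": [a.p_value for a in results],
            "star": [a.star for a in results],
        }
    )
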