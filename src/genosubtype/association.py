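"""Per-variant logistic association and the variant-level filters.

Each variant is tested one at a time with a logistic regression of disease
status on the additive genotype count (0/1/2 alternate alleles), adjusted
for age, sex and BMI.  Downstream filters keep variants that are
significantly *risk-increasing* (positive log-odds), rare in a reference
panel, or annotated deleterious by at least one gene-model source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .synthetic import DELETERIOUS_CLASSES, ANNOTATION_CLASSES

__all__ = [
    "AssociationResult",
    "fit_variant_logistic",
    "select_by_association",
    "select_rare",
    "select_deleterious",
]

# A Wald standard error this large signals quasi-separation: the estimate is
# drifting to infinity and the p-value is meaningless.
_SE_DIVERGENCE_LIMIT = 100.0


@dataclass
class AssociationResult:
    """Wald summary of one per-variant logistic fit."""

    variant_id: str
    beta: float
    se: float
    p_value: float
    converged: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"{self.variant_id}: p_value outside [0,1]")
            if not self.se > 0:
                raise ValueError(f"{self.variant_id}: non-positive standard error")


def _covariate_design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus covariate columns, dropping constant columns.

    Constant covariate columns are collinear with the intercept; dropping
    them lets callers pass all-zero or all-constant covariates to request an
    unadjusted fit.
    """
    cols = [np.ones(n)]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != n:
            raise ValueError("covariates and status have different numbers of subjects")
        for j in range(covariates.shape[1]):
            col = covariates[:, j]
            if np.ptp(col) > 0:
                cols.append(col)
    return np.column_stack(cols)


def fit_variant_logistic(
    genotypes: pd.DataFrame | np.ndarray,
    status: Sequence[int] | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> list[AssociationResult]:
    """Fit logit P(status=1) = a0 + a'X + b*G separately for every variant.

    Genotypes must be complete (impute missing calls first).  Monomorphic
    variants and fits that fail to converge (including quasi-separation)
    are returned with ``converged=False`` and never an exception, so a
    genome-scale loop cannot be derailed by one bad variant.
    """
    if isinstance(genotypes, pd.DataFrame):
        variant_ids = [str(c) for c in genotypes.columns]
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        variant_ids = [f"v{j}" for j in range(G.shape[1])]
    y = np.asarray(status, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("status must be binary 0/1")
    if classes.size < 2:
        raise ValueError("status contains a single class; association is undefined")
    if G.shape[0] != y.shape[0]:
        raise ValueError("genotypes and status have different numbers of subjects")
    if np.isnan(G).any():
        raise ValueError("genotypes contain missing values; impute before fitting")
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    base = _covariate_design(covariates, y.shape[0])

    results: list[AssociationResult] = []
    for j, vid in enumerate(variant_ids):
        g = G[:, j]
        if np.ptp(g) == 0:
            results.append(AssociationResult(vid, np.nan, np.nan, np.nan, False, "degenerate"))
            continue
        X = np.column_stack([base, g])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", ConvergenceWarning)
                fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            results.append(AssociationResult(vid, np.nan, np.nan, np.nan, False, "separation"))
            continue
        except Exception:
            results.append(AssociationResult(vid, np.nan, np.nan, np.nan, False, "fit_failure"))
            continue
        beta = float(fit.params[-1])
        se = float(fit.bse[-1])
        p = float(fit.pvalues[-1])
        ok = (
            bool(fit.mle_retvals.get("converged", False))
            and np.isfinite(beta)
            and np.isfinite(se)
            and 0 < se < _SE_DIVERGENCE_LIMIT
        )
        if not ok:
            results.append(AssociationResult(vid, np.nan, np.nan, np.nan, False, "nonconvergence"))
        else:
            results.append(AssociationResult(vid, beta, se, p, True))
    return results


def select_by_association(
    results: Iterable[AssociationResult],
    p_cutoff: float,
    positive_only: bool = True,
) -> set[str]:
    """Keep converged variants with p < cutoff (and beta > 0 if requested).

    The positive-effect rule discards protective variants: only alleles that
    raise disease odds are informative for subdividing the patients.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError(f"p_cutoff must be in (0,1), got {p_cutoff!r}")
    kept = set()
    for r in results:
        if not r.converged:
            continue
        if r.p_value < p_cutoff and (not positive_only or r.beta > 0):
            kept.add(r.variant_id)
    return kept


def select_rare(annotation: pd.DataFrame, threshold: float = 0.01) -> set[str]:
    """Variants with reference-panel minor-allele frequency strictly below threshold.

    The frequency is folded, min(f, 1-f), so the rule does not depend on
    which allele the panel reports.
    """
    if "reference_freq" not in annotation.columns:
        raise ValueError("annotation lacks a reference_freq column")
    freq = annotation["reference_freq"].to_numpy(dtype=float)
    if np.isnan(freq).any() or (freq < 0).any() or (freq > 1).any():
        raise ValueError("reference_freq must lie in [0,1] with no missing values")
    maf = np.minimum(freq, 1.0 - freq)
    return set(annotation.loc[maf < threshold, "variant_id"])


def select_deleterious(annotation: pd.DataFrame) -> set[str]:
    """Variants annotated nonsynonymous/stopgain/stoploss by >= 1 of 3 sources."""
    cols = ["class_source1", "class_source2", "class_source3"]
    missing = [c for c in cols if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks class columns: {missing}")
    values = annotation[cols].to_numpy(dtype=object)
    bad = sorted({str(v) for v in values.ravel() if v not in ANNOTATION_CLASSES})
    if bad:
        raise ValueError(f"unknown functional class value(s): {bad}")
    deleterious = np.isin(values, DELETERIOUS_CLASSES).any(axis=1)
    return set(annotation.loc[deleterious, "variant_id"])
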