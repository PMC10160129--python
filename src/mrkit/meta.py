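"""Cross-cohort pooling and multiple-testing control.

Per-outcome estimates from independent cohorts are pooled with
fixed-effects inverse-variance meta-analysis; across-cohort heterogeneity
is summarised by Cochran's Q. Families of pooled p-values are adjusted
with the Benjamini-Hochberg step-up procedure, and each association is
classified: BH-adjusted p < 0.05 is *significant*, nominal p < 0.05 with
adjusted p >= 0.05 is *suggestive*, anything else is *null*. The boundary
q == 0.05 is deliberately not significant (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptySetError
from .estimators import MREstimate

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NULL = "null"


@dataclass
class MetaResult:
    """Pooled estimate for one outcome with multiplicity bookkeeping."""

    outcome: str
    cohort_estimates: list[tuple[str, MREstimate]]
    pooled: MREstimate
    het_q: float
    het_p: float
    p_adjusted: float | None = None
    classification: str | None = None


def fixed_effect_meta(
    estimates: list[MREstimate],
) -> tuple[MREstimate, float, float]:
    """Inverse-variance fixed-effects pooling.

    pooled beta = sum(w_i b_i)/sum(w_i), pooled SE = sum(w_i)^-1/2 with
    w_i = se_i^-2; heterogeneity het_q = sum w_i (b_i - pooled)^2 on k-1
    df. A single estimate passes through unchanged with heterogeneity
    undefined (NaN).
    """
    if not estimates:
        raise EmptySetError("cannot pool an empty list of estimates")
    if len(estimates) == 1:
        return estimates[0], float("nan"), float("nan")
    b = np.array([e.beta for e in estimates])
    w = np.array([e.se for e in estimates]) ** -2.0
    pooled_beta = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    het_q = float(np.sum(w * (b - pooled_beta) ** 2))
    het_p = float(stats.chi2.sf(het_q, len(estimates) - 1))
    nsnp = int(sum(e.nsnp for e in estimates))
    pooled = MREstimate.from_beta_se("meta", pooled_beta, pooled_se, nsnp)
    return pooled, het_q, het_p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_association(p: float, q: float, alpha: float = 0.05) -> str:
    """Significant / suggestive / null per the FDR classification rule."""
    if q < alpha:
        return SIGNIFICANT
    if p < alpha:
        return SUGGESTIVE
    return NULL


def annotate_family(results: list[MetaResult], alpha: float = 0.05) -> list[MetaResult]:
    """BH-adjust the pooled p-values of a family in place and classify."""
    if not results:
        return results
    q = bh_adjust([r.pooled.pvalue for r in results])
    for r, qi in zip(results, q):
        r.p_adjusted = float(qi)
        r.classification = classify_association(r.pooled.pvalue, float(qi), alpha)
    return results
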