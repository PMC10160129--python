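"""Multivariable MR and two-step mediation decomposition.

Multivariable MR (MVMR) regresses the outcome associations by_j jointly on
the instrument associations with several exposures (the primary exposure
plus one or more mediators), without intercept and weighted by se_y^-2.
Coefficient k is the direct effect of exposure k conditional on the others.

The two-step mediation decomposition for an exposure X, mediator M and
outcome Y:

* total effect: univariable IVW of X on Y;
* alpha: univariable IVW of X on M;
* beta_med: effect of M on Y adjusted for X, from MVMR;
* indirect effect = alpha * beta_med (product of coefficients);
* proportion mediated = indirect / total, on the log-odds scale —
  deliberately unclamped, so negative proportions and proportions above 1
  pass through reporting unchanged.

With several mediators the combined indirect effect sums the per-path
products alpha_k * beta_med_k using the jointly adjusted MVMR
coefficients; the direct effect is the exposure coefficient from the same
joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import CollinearityError, NotEstimableError
from .estimators import MREstimate, ivw
from .instruments import HarmonizedSet, harmonize, select_instruments
from .summstats import SummaryTable

#: weighted-design condition number above which MVMR refuses to fit
CONDITION_LIMIT = 1e8


@dataclass
class MVMRInput:
    """Per-SNP association matrix for one outcome and >=1 exposures."""

    snp_ids: np.ndarray
    exposure_names: tuple[str, ...]
    bx: np.ndarray  # (J, k)
    se_x: np.ndarray  # (J, k)
    by: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.by) > 1:
            self.bx = self.bx.T
        self.se_x = np.asarray(self.se_x, dtype=float).reshape(self.bx.shape)
        self.by = np.asarray(self.by, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        J, k = self.bx.shape
        if len(self.by) != J or len(self.se_y) != J:
            raise ValueError("outcome vectors must match exposure-matrix rows")
        if len(self.exposure_names) != k:
            raise ValueError("one exposure name per matrix column required")
        if np.all(self.bx == 0, axis=0).any():
            raise ValueError("an exposure column is entirely zero")

    @property
    def n_snps(self) -> int:
        return self.bx.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]


@dataclass
class MediationResult:
    """Two-step MR decomposition for one exposure -> mediator(s) -> outcome."""

    outcome_name: str
    mediators: tuple[str, ...]
    total: MREstimate
    alpha: tuple[MREstimate, ...]
    beta_med: tuple[MREstimate, ...]
    direct: MREstimate
    indirect_beta: float
    indirect_se: float | None
    proportion_mediated: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total.beta == 0:
            raise NotEstimableError(
                f"total effect on {self.outcome_name!r} is zero; proportion undefined"
            )
        self.proportion_mediated = self.indirect_beta / self.total.beta


def mvmr_fit(mvin: MVMRInput) -> list[MREstimate]:
    """Zero-intercept weighted multivariable regression of by on the exposures.

    Weights se_y^-2; SEs from the weighted normal equations with residual
    dispersion (J - k df) floored at 1, matching the univariable IVW
    convention. A single-column input therefore reduces exactly to IVW.
    """
    J, k = mvin.bx.shape
    if J < k + 1:
        raise ValueError(f"MVMR needs more instruments ({J}) than exposures ({k})")
    w = mvin.se_y**-2
    Xw = mvin.bx * np.sqrt(w)[:, None]
    if np.linalg.cond(Xw) > CONDITION_LIMIT:
        raise CollinearityError("exposure columns are collinear in the weighted design")
    fit = sm.WLS(mvin.by, mvin.bx, weights=w).fit()
    phi = max(1.0, float(fit.scale))
    cov = np.asarray(fit.normalized_cov_params) * phi
    se = np.sqrt(np.diag(cov))
    return [
        MREstimate.from_beta_se("mvmr", b, s, J)
        for b, s in zip(np.atleast_1d(fit.params), np.atleast_1d(se))
    ]


def build_mvmr_input(
    exposures: list[tuple[str, SummaryTable]],
    outcome: SummaryTable,
    instrument_ids: list[str] | None = None,
    p_threshold: float = 5e-8,
    strand: str = "complement",
) -> MVMRInput:
    """Pool instruments across exposures and harmonize all tables jointly.

    Instruments are the union of each exposure's genome-wide-significant
    SNPs (or ``instrument_ids`` if given). The first exposure's records
    define the reference effect allele; every other exposure and the
    outcome are aligned to it with the pairwise harmonizer, and any SNP
    missing from (or unalignable in) any constituent GWAS is dropped.
    """
    if len(exposures) < 1:
        raise ValueError("at least one exposure required")
    if instrument_ids is None:
        ids: list[str] = []
        seen: set[str] = set()
        for _, tab in exposures:
            sel = select_instruments(tab, p_threshold=p_threshold)
            for s in sel.data["snp_id"]:
                if s not in seen:
                    seen.add(s)
                    ids.append(s)
        instrument_ids = ids

    ref_name, ref_table = exposures[0]
    ref = ref_table.restrict(instrument_ids)
    aligned: list[HarmonizedSet] = []
    for _, tab in list(exposures[1:]) + [("outcome", outcome)]:
        aligned.append(harmonize(ref, tab, strand=strand))

    common = set(ref.data["snp_id"])
    for hs in aligned:
        common &= set(hs.snp_ids)
    order = [s for s in ref.data["snp_id"] if s in common]
    if not order:
        raise NotEstimableError("no SNP shared by all exposures and the outcome")

    ref_idx = ref.data.set_index("snp_id").loc[order]
    cols_b = [ref_idx["beta"].to_numpy(float)]
    cols_s = [ref_idx["se"].to_numpy(float)]
    for hs in aligned[:-1]:
        pos = {s: i for i, s in enumerate(hs.snp_ids)}
        sel = [pos[s] for s in order]
        cols_b.append(hs.by[sel])
        cols_s.append(hs.se_y[sel])
    out = aligned[-1]
    pos = {s: i for i, s in enumerate(out.snp_ids)}
    sel = [pos[s] for s in order]

    return MVMRInput(
        snp_ids=np.asarray(order),
        exposure_names=tuple(name for name, _ in exposures),
        bx=np.column_stack(cols_b),
        se_x=np.column_stack(cols_s),
        by=out.by[sel],
        se_y=out.se_y[sel],
    )


def _product_se(a: MREstimate, b: MREstimate) -> float:
    # first-order delta method for the product of two independent estimates
    return float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))


def mediation_analysis(
    hs_exposure_outcome: HarmonizedSet,
    hs_exposure_mediator: HarmonizedSet,
    mvin: MVMRInput,
) -> MediationResult:
    """Two-step MR for a single mediator.

    ``mvin`` must contain exactly two exposure columns: the primary
    exposure first, the mediator second.
    """
    if mvin.n_exposures != 2:
        raise ValueError("single-mediator analysis expects a 2-column MVMR input")
    total = ivw(hs_exposure_outcome)
    alpha = ivw(hs_exposure_mediator)
    direct, beta_med = mvmr_fit(mvin)
    indirect = alpha.beta * beta_med.beta
    return MediationResult(
        outcome_name=hs_exposure_outcome.outcome_name,
        mediators=(mvin.exposure_names[1],),
        total=total,
        alpha=(alpha,),
        beta_med=(beta_med,),
        direct=direct.retagged("mvmr_direct"),
        indirect_beta=indirect,
        indirect_se=_product_se(alpha, beta_med),
    )


def combined_mediation(
    hs_exposure_outcome: HarmonizedSet,
    alphas: list[MREstimate],
    mvin: MVMRInput,
) -> MediationResult:
    """Joint decomposition across all mediators.

    ``alphas`` are the univariable exposure->mediator estimates, in the
    order of the mediator columns of ``mvin`` (columns 2..k). The combined
    indirect effect sums the per-path products alpha_k * beta_med_k with
    the jointly adjusted MVMR coefficients.
    """
    k = mvin.n_exposures - 1
    if len(alphas) != k:
        raise ValueError(f"expected {k} mediator alpha estimates, got {len(alphas)}")
    total = ivw(hs_exposure_outcome)
    fits = mvmr_fit(mvin)
    direct, betas = fits[0], fits[1:]
    indirect = float(sum(a.beta * b.beta for a, b in zip(alphas, betas)))
    se_ind = float(np.sqrt(sum(_product_se(a, b) ** 2 for a, b in zip(alphas, betas))))
    return MediationResult(
        outcome_name=hs_exposure_outcome.outcome_name,
        mediators=tuple(mvin.exposure_names[1:]),
        total=total,
        alpha=tuple(alphas),
        beta_med=tuple(betas),
        direct=direct.retagged("mvmr_direct"),
        indirect_beta=indirect,
        indirect_se=se_ind,
    )
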