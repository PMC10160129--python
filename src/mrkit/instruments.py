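"""Instrument selection and exposure/outcome allele harmonization.

Instruments are SNPs associated with the exposure at genome-wide
significance (p < 5e-8, strict) and mutually independent (pairwise
r^2 <= 0.01 after greedy pruning in ascending-p order). Harmonization
aligns each outcome record to the exposure's effect allele: swapped
alleles flip the outcome beta sign, strand mismatches are resolved by
complementing the outcome alleles once (configurable), and palindromic
(A/T, C/G) SNPs — whose strand cannot be read off the alleles — are
oriented by allele frequency, or dropped as ambiguous when the minor
allele frequency lies strictly inside (0.42, 0.58) or a frequency is
missing.

Every input instrument is accounted for: retained + dropped(missing) +
dropped(palindromic-ambiguous) + dropped(allele-mismatch) equals the
input count, and harmonizing an already-harmonized pair is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EmptyHarmonizationError, EmptyInstrumentError
from .summstats import SummaryTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default ambiguity window for palindromic SNPs (exclusive bounds)
AMBIGUITY_WINDOW = (0.42, 0.58)

GENOME_WIDE_P = 5e-8
LD_R2_THRESHOLD = 0.01

RETAIN_ALIGNED = "retain_aligned"
RETAIN_FLIPPABLE = "retain_flippable"
DROP_AMBIGUOUS = "drop_ambiguous"


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure and outcome effects, ready for estimation.

    Betas are oriented to the exposure effect allele (stored in
    ``effect_allele``/``other_allele``); ``eaf`` is the aligned outcome
    effect-allele frequency where available.
    """

    exposure_name: str
    outcome_name: str
    snp_ids: np.ndarray
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    eaf: np.ndarray | None = None
    n_input: int = 0
    n_dropped_missing: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0
    n_flipped: int = 0

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        for name in ("bx", "se_x", "by", "se_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.bx)
        if n < 1:
            raise EmptyHarmonizationError(
                f"no instruments in harmonized set {self.exposure_name} -> {self.outcome_name}"
            )
        if not (len(self.se_x) == len(self.by) == len(self.se_y) == len(self.snp_ids) == n):
            raise ValueError("harmonized arrays must have equal length")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")
        if self.n_input == 0:
            self.n_input = n

    def __len__(self) -> int:
        return len(self.bx)

    @classmethod
    def from_arrays(
        cls,
        bx,
        se_x,
        by,
        se_y,
        snp_ids=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        bx = np.asarray(bx, dtype=float)
        if snp_ids is None:
            snp_ids = np.array([f"snp{i}" for i in range(len(bx))])
        return cls(exposure_name, outcome_name, np.asarray(snp_ids), bx, se_x, by, se_y)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        """Boolean subset keeping bookkeeping counts of the parent."""
        hs = HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            self.snp_ids[mask],
            self.bx[mask],
            self.se_x[mask],
            self.by[mask],
            self.se_y[mask],
            effect_allele=None if self.effect_allele is None else self.effect_allele[mask],
            other_allele=None if self.other_allele is None else self.other_allele[mask],
            eaf=None if self.eaf is None else self.eaf[mask],
            n_input=self.n_input,
        )
        return hs

    def to_outcome_table(self, trait_type: str = "binary") -> SummaryTable:
        """Re-express the aligned outcome effects as a SummaryTable.

        Useful for idempotence checks and for feeding harmonized data back
        through file-based interfaces. Requires allele information.
        """
        if self.effect_allele is None:
            raise ValueError("harmonized set lacks allele information")
        from scipy import stats

        z = np.abs(self.by) / self.se_y
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "eaf": self.eaf if self.eaf is not None else np.nan,
                "beta": self.by,
                "se": self.se_y,
                "pvalue": np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0),
            }
        )
        return SummaryTable(trait_name=self.outcome_name, data=df, trait_type=trait_type)


def is_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float | None,
    window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> str:
    """Classify an allele pair for harmonization.

    Returns ``retain_aligned`` for non-palindromic pairs,
    ``drop_ambiguous`` for palindromic pairs whose frequency lies strictly
    inside the ambiguity window (or is missing), and ``retain_flippable``
    for palindromic pairs that frequency can orient.
    """
    if COMPLEMENT[effect_allele] != other_allele:
        return RETAIN_ALIGNED
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return DROP_AMBIGUOUS
    lo, hi = window
    if lo < eaf < hi:
        return DROP_AMBIGUOUS
    return RETAIN_FLIPPABLE


def select_instruments(
    table: SummaryTable,
    p_threshold: float = GENOME_WIDE_P,
    ld: pd.DataFrame | Callable[[str, str], float] | None = None,
    r2_threshold: float = LD_R2_THRESHOLD,
) -> SummaryTable:
    """Genome-wide-significant, LD-independent instruments, ascending p.

    SNPs with p strictly below ``p_threshold`` are retained and greedily
    pruned in ascending-p order (ties broken by snp_id): a SNP is removed
    when its r^2 with any already-kept SNP exceeds ``r2_threshold``. With
    ``ld=None`` the table is assumed pre-pruned.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    df = table.data[table.data["pvalue"] < p_threshold]
    if df.empty:
        raise EmptyInstrumentError(
            f"no SNP passes p < {p_threshold:g} for trait {table.trait_name!r}"
        )
    df = df.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(drop=True)

    if ld is not None:
        if isinstance(ld, pd.DataFrame):
            def r2(a: str, b: str) -> float:
                try:
                    return float(ld.loc[a, b])
                except KeyError:
                    return 0.0
        else:
            r2 = ld
        kept: list[str] = []
        keep_mask = []
        for snp in df["snp_id"]:
            ok = all(r2(snp, k) <= r2_threshold for k in kept)
            keep_mask.append(ok)
            if ok:
                kept.append(snp)
        df = df[np.asarray(keep_mask)].reset_index(drop=True)

    return SummaryTable(
        trait_name=table.trait_name,
        data=df,
        trait_type=table.trait_type,
        n_cases=table.n_cases,
        n_controls=table.n_controls,
        n=table.n,
    )


def _complement_series(s: pd.Series) -> pd.Series:
    return s.map(COMPLEMENT)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    strand: str = "complement",
    window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Parameters
    ----------
    exposure
        Exposure table restricted to the selected instruments.
    outcome
        Outcome (or mediator) summary table; SNPs absent here are dropped.
    strand
        ``"complement"`` (default) resolves strand mismatches by
        complementing the outcome alleles once; ``"drop"`` discards them
        as mismatches instead.
    """
    if strand not in ("complement", "drop"):
        raise ValueError("strand must be 'complement' or 'drop'")
    if exposure.n_snps == 0:
        raise EmptyHarmonizationError("exposure instrument table is empty")

    e = exposure.data
    m = e.merge(outcome.data, on="snp_id", how="inner", suffixes=("_x", "_y"))
    n_input = len(e)
    n_missing = n_input - len(m)

    if m.empty:
        raise EmptyHarmonizationError(
            f"no instrument of {exposure.trait_name!r} found in {outcome.trait_name!r}"
        )

    Ea, Eo = m["effect_allele_x"], m["other_allele_x"]
    oa_e, oa_o = m["effect_allele_y"], m["other_allele_y"]
    pal = _complement_series(Eo) == Ea

    by = m["beta_y"].to_numpy(float).copy()
    eaf_y = m["eaf_y"].to_numpy(float).copy()
    eaf_x = m["eaf_x"].to_numpy(float)

    flipped = np.zeros(len(m), dtype=bool)
    drop_pal = np.zeros(len(m), dtype=bool)
    drop_mm = np.zeros(len(m), dtype=bool)

    # --- non-palindromic pairs: resolve by allele letters -----------------
    same = (oa_e == Ea) & (oa_o == Eo)
    swapped = (oa_e == Eo) & (oa_o == Ea)
    comp_same = (_complement_series(oa_e) == Ea) & (_complement_series(oa_o) == Eo)
    comp_swapped = (_complement_series(oa_e) == Eo) & (_complement_series(oa_o) == Ea)
    np_mask = (~pal).to_numpy()
    if strand == "drop":
        comp_same = comp_same & False
        comp_swapped = comp_swapped & False
    flip_np = (swapped | comp_swapped).to_numpy() & np_mask
    ok_np = (same | swapped | comp_same | comp_swapped).to_numpy() & np_mask
    drop_mm |= np_mask & ~ok_np
    flipped |= flip_np

    # --- palindromic pairs: resolve by frequency --------------------------
    pal_np = pal.to_numpy()
    # outcome pair must be the same unordered pair (its complement is itself)
    pair_ok = (
        ((oa_e == Ea) | (oa_e == Eo)).to_numpy()
        & ((oa_o == Ea) | (oa_o == Eo)).to_numpy()
        & (oa_e != oa_o).to_numpy()
    )
    drop_mm |= pal_np & ~pair_ok

    cand = pal_np & pair_ok
    # frequency used for the ambiguity rule: outcome EAF when present, else exposure
    f_rule = np.where(np.isnan(eaf_y), eaf_x, eaf_y)
    lo, hi = window
    unresolvable = np.isnan(eaf_y) | np.isnan(eaf_x) | ((f_rule > lo) & (f_rule < hi))
    drop_pal |= cand & unresolvable
    orient = cand & ~unresolvable
    # aligned when the outcome effect allele has the same minor/major status
    # as the exposure effect allele; otherwise flip
    discordant = orient & ((eaf_y < 0.5) != (eaf_x < 0.5))
    flipped |= discordant

    by[flipped] = -by[flipped]
    eaf_y[flipped] = 1.0 - eaf_y[flipped]

    keep = ~(drop_pal | drop_mm)
    n_pal = int(drop_pal.sum())
    n_mm = int(drop_mm.sum())
    n_flip = int((flipped & keep).sum())
    if not keep.any():
        raise EmptyHarmonizationError(
            f"no instrument survives harmonization of {exposure.trait_name!r} "
            f"against {outcome.trait_name!r}"
        )
    for snp, reason in zip(m["snp_id"][drop_pal], np.repeat("ambiguous_palindrome", n_pal)):
        logger.info("harmonize %s->%s: dropped %s (%s)", exposure.trait_name, outcome.trait_name, snp, reason)

    kept = m[keep]
    hs = HarmonizedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        snp_ids=kept["snp_id"].to_numpy(),
        bx=kept["beta_x"].to_numpy(float),
        se_x=kept["se_x"].to_numpy(float),
        by=by[keep],
        se_y=kept["se_y"].to_numpy(float),
        effect_allele=kept["effect_allele_x"].to_numpy(),
        other_allele=kept["other_allele_x"].to_numpy(),
        eaf=eaf_y[keep],
        n_input=n_input,
        n_dropped_missing=n_missing,
        n_dropped_palindromic=n_pal,
        n_dropped_mismatch=n_mm,
        n_flipped=n_flip,
    )
    return hs
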