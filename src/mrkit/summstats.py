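"""GWAS summary-statistics input/output.

A summary-statistics table holds one row per SNP with seven semantic
columns: ``snp_id``, ``effect_allele``, ``other_allele``, ``eaf`` (effect
allele frequency, may be missing), ``beta`` (log-odds for binary traits, SD
units for continuous), ``se`` and ``pvalue``. Files are plain delimited
text (tab or comma, sniffed from the header) with arbitrary column names
remapped through a ``column_map``.

Rows violating the per-record invariants (invalid or equal alleles,
non-positive SE, p-value outside (0, 1], frequency outside [0, 1],
duplicated identifier) are dropped on read, counted by reason, and logged —
never silently discarded without a trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: the seven semantic columns every summary table must provide
SEMANTIC_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
)

#: canonical column order of a results table (one row per outcome/method)
RESULT_COLUMNS = (
    "outcome",
    "method",
    "nsnp",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "pvalue",
    "p_adjusted",
    "classification",
)


@dataclass
class SummaryTable:
    """A validated GWAS summary-statistics table for one trait.

    ``data`` is a DataFrame with exactly the :data:`SEMANTIC_COLUMNS`;
    ``drop_counts`` records how many input rows were discarded per reason
    during :func:`read_summary_table`.
    """

    trait_name: str
    data: pd.DataFrame
    trait_type: str = "binary"
    n_cases: int | None = None
    n_controls: int | None = None
    n: int | None = None
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        missing = [c for c in SEMANTIC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(
                f"summary table for {self.trait_name!r} lacks columns {missing}"
            )
        self.data = self.data.loc[:, list(SEMANTIC_COLUMNS)].reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_counts.values())

    def restrict(self, snp_ids: Iterable[str]) -> "SummaryTable":
        """Subset to ``snp_ids``, preserving the given order; absent ids are skipped."""
        idx = self.data.set_index("snp_id")
        keep = [s for s in snp_ids if s in idx.index]
        sub = idx.loc[keep].reset_index()
        return SummaryTable(
            trait_name=self.trait_name,
            data=sub,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n=self.n,
        )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorised invariant enforcement; returns (clean frame, drop counts)."""
    counts: dict[str, int] = {}
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            counts[reason] = counts.get(reason, 0) + n
            logger.info("dropping %d rows: %s", n, reason)
            df = df.loc[~mask]

    valid = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(
        VALID_ALLELES
    )
    _drop(~valid, "invalid_or_multiallelic_allele")
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    _drop(~(df["se"] > 0) | df["beta"].isna(), "nonpositive_or_missing_se_or_beta")
    _drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    bad_eaf = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    _drop(bad_eaf, "eaf_out_of_range")
    # duplicate identifiers: first occurrence wins (logged)
    _drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")

    n_missing_eaf = int(df["eaf"].isna().sum())
    if n_missing_eaf:
        logger.warning(
            "%d rows have missing EAF; palindromic SNPs among them will be "
            "dropped as ambiguous during harmonization",
            n_missing_eaf,
        )
    return df.reset_index(drop=True), counts


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "binary",
    **meta: int | None,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a :class:`SummaryTable`.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Mapping from semantic name (:data:`SEMANTIC_COLUMNS`) to the file's
        column name. Omitted entries default to the semantic name itself.
    trait_name, trait_type, **meta
        Trait metadata (``n``, ``n_cases``, ``n_controls``).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"empty summary-statistics file: {path}")
    sep = _sniff_delimiter(header)
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    if raw.empty:
        raise InputError(f"summary-statistics file has no data rows: {path}")

    cmap = {c: c for c in SEMANTIC_COLUMNS}
    if column_map:
        cmap.update(column_map)
    for semantic, actual in cmap.items():
        if actual not in raw.columns:
            raise ConfigurationError(
                f"column {actual!r} (mapped to {semantic!r}) missing from {path}"
            )
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    df["snp_id"] = df["snp_id"].astype(str)
    clean, counts = validate_records(df)
    if clean.empty:
        raise InputError(f"no valid rows remain after validation: {path}")
    return SummaryTable(
        trait_name=trait_name or path.stem,
        data=clean,
        trait_type=trait_type,
        n_cases=meta.get("n_cases"),
        n_controls=meta.get("n_controls"),
        n=meta.get("n"),
        drop_counts=counts,
    )


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write a summary table as tab-delimited text with full float precision."""
    table.data.loc[:, list(SEMANTIC_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_results(results: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write per-outcome result rows in the canonical 9-column order.

    Floats are serialised with ``repr`` precision so a write→read→write cycle
    is byte-identical.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(list(results))
    if df.empty:
        df = pd.DataFrame(columns=list(RESULT_COLUMNS))
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"result rows lack fields {missing}")
    df.loc[:, list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`.

    ``keep_default_na=False`` so the classification label ``"null"`` is not
    mistaken for a missing value; empty fields are still missing.
    """
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
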