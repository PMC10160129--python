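"""Study orchestration: harmonize, estimate, pool, adjust, mediate, report.

``run_study`` executes the full analysis a liability-to-disease MR study
performs: for every (outcome, cohort) pair it harmonizes the exposure
instruments against the cohort GWAS and runs IVW, MR-Egger, the weighted
median, Cochran's Q and MR-PRESSO; per outcome it pools the cohort IVW
estimates with fixed-effects meta-analysis; across outcomes it applies
Benjamini-Hochberg and the significant/suggestive classification; and for
outcomes classified significant it runs the two-step mediation analysis
for each configured mediator plus the jointly adjusted combination.

A stage failure for one outcome is logged and the run continues — partial
results are valid output. All randomness is seeded from the run config, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import meta as meta_mod
from .errors import ConfigurationError, MRKitError
from .estimators import (
    cochran_q,
    ivw,
    mr_egger,
    mr_presso,
    to_odds_ratio,
    weighted_median,
    MREstimate,
)
from .instruments import harmonize, select_instruments
from .mediation import build_mvmr_input, combined_mediation, mediation_analysis
from .meta import MetaResult, annotate_family, fixed_effect_meta
from .summstats import read_summary_table, write_results

logger = logging.getLogger(__name__)

PER_COHORT_COLUMNS = (
    "outcome", "cohort", "method", "nsnp", "beta", "se",
    "odds_ratio", "ci_low", "ci_high", "pvalue",
)

MEDIATION_COLUMNS = (
    "outcome", "mediator", "total_beta", "direct_beta", "direct_or",
    "alpha_beta", "beta_med", "indirect_beta", "indirect_se",
    "proportion_mediated",
)


@dataclass
class RunConfig:
    """Validated study configuration (see ``load_run_config`` for the file format)."""

    exposure_file: Path
    exposure_name: str = "exposure"
    exposure_column_map: dict | None = None
    outcomes: list[dict] = field(default_factory=list)
    mediators: list[dict] = field(default_factory=list)
    p_instrument: float = 5e-8
    ld_r2: float = 0.01
    alpha: float = 0.05
    n_boot: int = 1000
    presso_k: int = 1000
    seed: int = 0
    output_dir: Path = Path("results")
    force_mediation: bool = False
    strand: str = "complement"
    ld_file: Path | None = None

    def validate(self) -> None:
        if not self.exposure_file.exists():
            raise ConfigurationError(f"exposure file missing: {self.exposure_file}")
        if not self.outcomes:
            raise ConfigurationError("at least one outcome must be configured")
        for out in self.outcomes:
            if not out.get("cohorts"):
                raise ConfigurationError(f"outcome {out.get('name')!r} has no cohorts")
            for coh in out["cohorts"]:
                if not Path(coh["file"]).exists():
                    raise ConfigurationError(f"missing cohort file: {coh['file']}")
        for med in self.mediators:
            if not Path(med["file"]).exists():
                raise ConfigurationError(f"missing mediator file: {med['file']}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; relative paths resolve next to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    thresholds = raw.get("thresholds", {})
    est = raw.get("estimators", {})
    cfg = RunConfig(
        exposure_file=_resolve(raw["exposure"]["file"]),
        exposure_name=raw["exposure"].get("name", "exposure"),
        exposure_column_map=raw["exposure"].get("column_map"),
        outcomes=[
            {
                "name": o["name"],
                "cohorts": [
                    {"label": c["label"], "file": str(_resolve(c["file"]))}
                    for c in o["cohorts"]
                ],
            }
            for o in raw.get("outcomes", [])
        ],
        mediators=[
            {"name": m["name"], "file": str(_resolve(m["file"])),
             "trait_type": m.get("trait_type", "continuous")}
            for m in raw.get("mediators", [])
        ],
        p_instrument=float(thresholds.get("p_instrument", 5e-8)),
        ld_r2=float(thresholds.get("ld_r2", 0.01)),
        alpha=float(thresholds.get("alpha", 0.05)),
        n_boot=int(est.get("n_boot", 1000)),
        presso_k=int(est.get("presso_k", 1000)),
        seed=int(est.get("seed", 0)),
        output_dir=_resolve(str(raw.get("output_dir", "results"))),
        force_mediation=bool(raw.get("force_mediation", False)),
        strand=raw.get("strand", "complement"),
        ld_file=_resolve(raw["ld_file"]) if raw.get("ld_file") else None,
    )
    cfg.validate()
    return cfg


def _est_row(outcome: str, cohort: str, est: MREstimate) -> dict:
    or_, lo, hi = to_odds_ratio(est)
    return {
        "outcome": outcome, "cohort": cohort, "method": est.method,
        "nsnp": est.nsnp, "beta": est.beta, "se": est.se,
        "odds_ratio": or_, "ci_low": lo, "ci_high": hi, "pvalue": est.pvalue,
    }


def _analyze_cohort(hs, config: RunConfig, log: list[str], outcome: str, label: str):
    """IVW + full sensitivity suite for one harmonized cohort."""
    rows = []
    est_ivw = ivw(hs)
    rows.append(_est_row(outcome, label, est_ivw))
    q, df, qp = cochran_q(hs, est_ivw)
    log.append(f"het\t{outcome}\t{label}\tQ={q:.6g}\tdf={df}\tp={qp:.6g}")
    try:
        slope, intercept = mr_egger(hs)
        rows.append(_est_row(outcome, label, slope))
        rows.append(_est_row(outcome, label, intercept))
    except MRKitError as exc:
        log.append(f"error\t{outcome}\t{label}\tegger\t{exc}")
    try:
        wm = weighted_median(hs, n_boot=config.n_boot, seed=config.seed)
        rows.append(_est_row(outcome, label, wm))
    except MRKitError as exc:
        log.append(f"error\t{outcome}\t{label}\tweighted_median\t{exc}")
    try:
        pr = mr_presso(hs, K=config.presso_k, seed=config.seed)
        rows.append(_est_row(outcome, label, pr.raw))
        rows.append(_est_row(outcome, label, pr.corrected))
        log.append(
            f"presso\t{outcome}\t{label}\tglobal_p={pr.global_p:.6g}\t"
            f"outliers={','.join(pr.outlier_snps) or '-'}"
        )
    except MRKitError as exc:
        log.append(f"error\t{outcome}\t{label}\tmr_presso\t{exc}")
    return rows, est_ivw


def run_study(config: RunConfig) -> Path:
    """Execute the configured study; returns the results directory."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed\t{config.seed}"]

    exposure = read_summary_table(
        config.exposure_file,
        column_map=config.exposure_column_map,
        trait_name=config.exposure_name,
    )
    ld = pd.read_csv(config.ld_file, sep=None, engine="python", index_col=0) \
        if config.ld_file else None
    instruments = select_instruments(
        exposure, p_threshold=config.p_instrument, ld=ld, r2_threshold=config.ld_r2
    )
    log.append(
        f"instruments\t{config.exposure_name}\t-\tn_in={exposure.n_snps}\t"
        f"n_out={instruments.n_snps}"
    )

    per_cohort_rows: list[dict] = []
    metas: list[MetaResult] = []
    hs_by_outcome: dict[str, list] = {}
    for out in config.outcomes:
        name = out["name"]
        cohort_estimates: list[tuple[str, MREstimate]] = []
        hs_by_outcome[name] = []
        for coh in out["cohorts"]:
            label = coh["label"]
            try:
                table = read_summary_table(coh["file"], trait_name=f"{name}_{label}")
                hs = harmonize(instruments, table, strand=config.strand)
                log.append(
                    f"harmonize\t{name}\t{label}\tn_in={hs.n_input}\t"
                    f"n_out={len(hs)}\tmissing={hs.n_dropped_missing}\t"
                    f"palindromic={hs.n_dropped_palindromic}\t"
                    f"mismatch={hs.n_dropped_mismatch}\tflipped={hs.n_flipped}"
                )
                rows, est_ivw = _analyze_cohort(hs, config, log, name, label)
                per_cohort_rows.extend(rows)
                cohort_estimates.append((label, est_ivw))
                hs_by_outcome[name].append((label, table, hs))
            except MRKitError as exc:
                log.append(f"error\t{name}\t{label}\tcohort\t{exc}")
        if not cohort_estimates:
            log.append(f"error\t{name}\t-\tpooling\tno cohort estimate available")
            continue
        pooled, het_q, het_p = fixed_effect_meta([e for _, e in cohort_estimates])
        metas.append(MetaResult(name, cohort_estimates, pooled, het_q, het_p))

    annotate_family(metas, alpha=config.alpha)

    pooled_rows = []
    for m in metas:
        or_, lo, hi = to_odds_ratio(m.pooled)
        pooled_rows.append(
            {
                "outcome": m.outcome, "method": "meta", "nsnp": m.pooled.nsnp,
                "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                "pvalue": m.pooled.pvalue, "p_adjusted": m.p_adjusted,
                "classification": m.classification,
            }
        )
        log.append(
            f"meta\t{m.outcome}\t-\tbeta={m.pooled.beta:.6g}\t"
            f"het_q={m.het_q:.6g}\tq={m.p_adjusted:.6g}\tclass={m.classification}"
        )

    mediation_rows = _run_mediation(config, instruments, exposure, metas, hs_by_outcome, log)

    pd.DataFrame(per_cohort_rows, columns=list(PER_COHORT_COLUMNS)).to_csv(
        out_dir / "per_cohort_results.tsv", sep="\t", index=False
    )
    write_results(pooled_rows, out_dir / "pooled_results.tsv")
    pd.DataFrame(mediation_rows, columns=list(MEDIATION_COLUMNS)).to_csv(
        out_dir / "mediation_results.tsv", sep="\t", index=False
    )
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return out_dir


def _run_mediation(config, instruments, exposure, metas, hs_by_outcome, log):
    """Two-step mediation for significant outcomes (or all when forced).

    With several cohorts per outcome the per-cohort MVMR coefficients are
    fixed-effects pooled before applying the product rule once against the
    pooled total effect.
    """
    if not config.mediators:
        return []
    mediator_tables = {
        m["name"]: read_summary_table(
            m["file"], trait_name=m["name"], trait_type=m.get("trait_type", "continuous")
        )
        for m in config.mediators
    }
    alphas: dict[str, MREstimate] = {}
    for name, table in mediator_tables.items():
        hs_xm = harmonize(instruments, table, strand=config.strand)
        alphas[name] = ivw(hs_xm)
        log.append(f"alpha\t{name}\t-\tbeta={alphas[name].beta:.6g}\tnsnp={alphas[name].nsnp}")

    rows = []
    for m in metas:
        if m.classification != meta_mod.SIGNIFICANT and not config.force_mediation:
            continue
        targets = list(mediator_tables.items())
        for med_name, med_table in targets + [("__combined__", None)]:
            try:
                direct_parts, bmed_parts = [], {}
                for label, out_table, hs in hs_by_outcome[m.outcome]:
                    if med_name == "__combined__":
                        exps = [(config.exposure_name, exposure)] + [
                            (n, t) for n, t in mediator_tables.items()
                        ]
                    else:
                        exps = [(config.exposure_name, exposure), (med_name, med_table)]
                    mvin = build_mvmr_input(
                        exps, out_table, p_threshold=config.p_instrument,
                        strand=config.strand,
                    )
                    from .mediation import mvmr_fit

                    fits = mvmr_fit(mvin)
                    direct_parts.append(fits[0])
                    for mname, fit in zip(mvin.exposure_names[1:], fits[1:]):
                        bmed_parts.setdefault(mname, []).append(fit)
                direct = fixed_effect_meta(direct_parts)[0]
                if med_name == "__combined__":
                    b_pooled = {n: fixed_effect_meta(v)[0] for n, v in bmed_parts.items()}
                    indirect = sum(alphas[n].beta * b_pooled[n].beta for n in b_pooled)
                    alpha_beta = float("nan")
                    bmed_beta = float("nan")
                    se_ind = float(
                        np.sqrt(sum(
                            alphas[n].beta ** 2 * b_pooled[n].se ** 2
                            + b_pooled[n].beta ** 2 * alphas[n].se ** 2
                            for n in b_pooled
                        ))
                    )
                    label_out = "combined"
                else:
                    b = fixed_effect_meta(bmed_parts[med_name])[0]
                    indirect = alphas[med_name].beta * b.beta
                    alpha_beta = alphas[med_name].beta
                    bmed_beta = b.beta
                    se_ind = float(
                        np.sqrt(alphas[med_name].beta ** 2 * b.se ** 2
                                + b.beta ** 2 * alphas[med_name].se ** 2)
                    )
                    label_out = med_name
                if m.pooled.beta == 0:
                    raise MRKitError("total effect is zero; proportion not estimable")
                rows.append(
                    {
                        "outcome": m.outcome, "mediator": label_out,
                        "total_beta": m.pooled.beta, "direct_beta": direct.beta,
                        "direct_or": float(np.exp(direct.beta)),
                        "alpha_beta": alpha_beta, "beta_med": bmed_beta,
                        "indirect_beta": float(indirect), "indirect_se": se_ind,
                        "proportion_mediated": float(indirect) / m.pooled.beta,
                    }
                )
            except MRKitError as exc:
                log.append(f"error\t{m.outcome}\t-\tmediation[{med_name}]\t{exc}")
    return rows


def report(results_dir: str | Path) -> str:
    """Human-readable study summary, outcomes sorted by descending pooled OR."""
    results_dir = Path(results_dir)
    pooled_path = results_dir / "pooled_results.tsv"
    if not pooled_path.exists():
        raise MRKitError(f"missing results table: {pooled_path}")
    # keep_default_na=False: the classification label "null" is data, not NaN
    pooled = pd.read_csv(pooled_path, sep="\t", keep_default_na=False, na_values=[""])
    lines = ["outcome\tOR (95% CI)\tp\tq\tclass"]
    if not pooled.empty:
        pooled = pooled.sort_values("odds_ratio", ascending=False, kind="mergesort")
        for _, r in pooled.iterrows():
            lines.append(
                f"{r['outcome']}\t{r['odds_ratio']:.3f} "
                f"({r['ci_low']:.3f}, {r['ci_high']:.3f})\t"
                f"{r['pvalue']:.3g}\t{r['p_adjusted']:.3g}\t{r['classification']}"
            )
    med_path = results_dir / "mediation_results.tsv"
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        if not med.empty:
            lines.append("")
            lines.append("mediation (significant outcomes)")
            lines.append("outcome\tmediator\tdirect OR\tproportion mediated")
            for _, r in med.iterrows():
                lines.append(
                    f"{r['outcome']}\t{r['mediator']}\t{r['direct_or']:.3f}\t"
                    f"{100 * r['proportion_mediated']:.2f}%"
                )
    return "\n".join(lines) + "\n"
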