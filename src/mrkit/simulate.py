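"""Synthetic two-sample GWAS summary statistics with known truth.

The generator emulates the statistical structure of a liability-scale MR
study: ~98 independent genome-wide-significant instruments for a large
binary exposure GWAS, binary outcomes on the log-odds scale observed in
2-3 independent cohorts, optional mediator GWAS, and configurable
horizontal pleiotropy. Effects are generated directly on the summary
scale — per SNP j with minor allele frequency maf_j, the standard error
of a GWAS of n individuals is se = 1/sqrt(2 n maf (1-maf)), and observed
betas are the true betas plus independent normal noise with that SE
(exposure and outcome noise independent: the two-sample design). No
individual-level genotypes are simulated and instruments are independent
by construction, as after LD clumping.

True instrument strength is drawn as a z-score (true beta over exposure
SE) uniform on ``z_range``; the default (8, 40) keeps every instrument's
expected exposure p-value far below 5e-8 without rejection sampling, so
selection on the observed p-value introduces no winner's curse.

Alleles are assigned randomly with a ~1/3 palindromic (A/T, C/G) rate,
and outcome tables randomly swap allele order or report the opposite
strand, so the harmonizer is genuinely exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .summstats import SummaryTable

_TINY = np.finfo(float).tiny

_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Pleiotropy:
    """Per-SNP direct (pleiotropic) outcome effects alpha_j.

    kinds: ``none``; ``balanced`` — alpha ~ N(0, sigma^2); ``directional``
    — alpha ~ N(mu, sigma^2); ``inside_violation`` — alpha correlated with
    instrument strength (correlation rho), violating the InSIDE assumption
    MR-Egger relies on.

    With ``scale_by_se`` the spread is expressed in units of each SNP's
    outcome standard error (alpha_j ~ N(mu, (sigma * se_yj)^2)), which is
    exactly the multiplicative over-dispersion model the IVW and Egger
    estimators assume; without it the pleiotropic variance is additive and
    the same for every SNP regardless of its precision.
    """

    kind: str = "none"
    mu: float = 0.0
    sigma: float = 0.0
    rho: float = 0.0
    scale_by_se: bool = False

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sigma: float = 0.005, scale_by_se: bool = False) -> "Pleiotropy":
        return cls("balanced", sigma=sigma, scale_by_se=scale_by_se)

    @classmethod
    def directional(cls, mu: float, sigma: float = 0.005) -> "Pleiotropy":
        return cls("directional", mu=mu, sigma=sigma)

    @classmethod
    def inside_violation(cls, rho: float, sigma: float = 0.005) -> "Pleiotropy":
        return cls("inside_violation", rho=rho, sigma=sigma)

    def draw(
        self,
        rng: np.random.Generator,
        gamma: np.ndarray,
        se_y: np.ndarray | None = None,
    ) -> np.ndarray:
        J = len(gamma)
        if self.kind == "none":
            return np.zeros(J)
        sigma = self.sigma
        if self.scale_by_se:
            if se_y is None:
                raise ConfigurationError("scale_by_se pleiotropy needs outcome SEs")
            sigma = self.sigma * se_y
        if self.kind == "balanced":
            return rng.normal(0.0, sigma, J)
        if self.kind == "directional":
            # mean pleiotropic effect is defined relative to the
            # exposure-increasing allele, as in oriented Egger regression
            return np.sign(gamma) * self.mu + rng.normal(0.0, sigma, J)
        if self.kind == "inside_violation":
            g = (gamma - gamma.mean()) / (gamma.std() or 1.0)
            noise = rng.normal(0.0, sigma, J)
            return self.rho * g * np.mean(np.atleast_1d(sigma)) + np.sqrt(1 - self.rho**2) * noise
        raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass
class MediationDesign:
    """Path coefficients for one exposure -> mediator -> outcome scenario.

    ``a``: exposure effect on the mediator; ``b``: mediator effect on the
    outcome; ``c``: direct exposure effect. The total effect is c + a*b and
    the true proportion mediated a*b/(c + a*b). ``J_med`` extra SNPs act on
    the mediator only.
    """

    a: float = 0.2
    b: float = 0.5
    c: float = 0.1
    J_med: int = 50
    n_mediator: int = 700_000

    @property
    def theta_total(self) -> float:
        return self.c + self.a * self.b

    @property
    def true_proportion(self) -> float:
        return self.a * self.b / self.theta_total


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic two-sample scenario.

    Defaults mirror a large-consortium liability GWAS (n = 807,553) read
    against biobank binary endpoints with an effective outcome sample size
    of 100,000, 98 instruments, and MAF uniform on (0.05, 0.5).
    """

    J: int = 98
    n_exposure: int = 807_553
    n_outcome: int = 100_000
    theta: float = 0.3
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    mediation: MediationDesign | None = None
    cohorts: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    z_range: tuple[float, float] = (8.0, 40.0)
    palindromic_rate: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 4:
            raise ConfigurationError("J must be >= 4")
        if min(self.n_exposure, self.n_outcome) < 1000:
            raise ConfigurationError("GWAS sample sizes must be >= 1000")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.cohorts < 1:
            raise ConfigurationError("at least one outcome cohort required")


def _gwas_se(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _TINY, 1.0)


def _assign_alleles(rng: np.random.Generator, J: int, pal_rate: float):
    pal = rng.random(J) < pal_rate
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    pal_idx = rng.integers(0, len(_PAL_PAIRS), J)
    np_idx = rng.integers(0, len(_NONPAL_PAIRS), J)
    for j in range(J):
        ea[j], oa[j] = _PAL_PAIRS[pal_idx[j]] if pal[j] else _NONPAL_PAIRS[np_idx[j]]
    return ea, oa


def _make_table(
    trait_name: str,
    snp_ids: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    trait_type: str = "binary",
    n: int | None = None,
) -> SummaryTable:
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _pvals(beta, se),
        }
    )
    return SummaryTable(trait_name=trait_name, data=df, trait_type=trait_type, n=n)


def _present_outcome(
    rng: np.random.Generator,
    ea: np.ndarray,
    oa: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
):
    """Randomly re-express records as another GWAS would report them.

    A third of records swap effect/other allele (beta negated, frequency
    complemented); an independent third are reported on the opposite
    strand (letters complemented, numbers unchanged).
    """
    J = len(ea)
    ea = ea.copy()
    oa = oa.copy()
    beta = beta.copy()
    eaf = eaf.copy()
    swap = rng.random(J) < 1.0 / 3.0
    strand = rng.random(J) < 1.0 / 3.0
    ea[swap], oa[swap] = oa[swap], ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    for j in np.nonzero(strand)[0]:
        ea[j] = _COMP[ea[j]]
        oa[j] = _COMP[oa[j]]
    return ea, oa, eaf, beta


def _draw_instruments(rng: np.random.Generator, config: ScenarioConfig, J: int, n: int):
    """MAF, alleles, true effects and observed exposure-scale draws for J SNPs."""
    maf = rng.uniform(*config.maf_range, J)
    se = _gwas_se(n, maf)
    z = rng.uniform(*config.z_range, J)
    sign = rng.choice([-1.0, 1.0], J)
    gamma = sign * z * se
    ea, oa = _assign_alleles(rng, J, config.palindromic_rate)
    eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)
    return maf, se, gamma, ea, oa, eaf


def simulate_two_sample(config: ScenarioConfig):
    """Exposure table, one outcome table per cohort, and the truth record.

    Outcome cohorts share the true per-SNP effects theta*gamma_j + alpha_j
    but have independent sampling noise and independently scrambled allele
    presentation.
    """
    rng = np.random.default_rng(config.seed)
    maf, se_x, gamma, ea, oa, eaf = _draw_instruments(rng, config, config.J, config.n_exposure)
    bx = rng.normal(gamma, se_x)
    exposure = _make_table("exposure", _snp_ids(config.J), ea, oa, eaf, bx, se_x,
                           n=config.n_exposure)

    se_y = _gwas_se(config.n_outcome, maf)
    alpha = config.pleiotropy.draw(rng, gamma, se_y)
    outcomes = []
    for c in range(config.cohorts):
        by = rng.normal(config.theta * gamma + alpha, se_y)
        eaf_c = np.clip(eaf + rng.normal(0.0, 0.005, config.J), 0.001, 0.999)
        ea_c, oa_c, eaf_c, by_c = _present_outcome(rng, ea, oa, eaf_c, by)
        outcomes.append(
            _make_table(f"outcome_cohort{c + 1}", _snp_ids(config.J), ea_c, oa_c,
                        eaf_c, by_c, se_y, n=config.n_outcome)
        )
    truth = {
        "theta": config.theta,
        "gamma": gamma,
        "alpha": alpha,
        "maf": maf,
        "snp_ids": _snp_ids(config.J),
    }
    return exposure, outcomes, truth


def _snp_ids(J: int, offset: int = 0) -> np.ndarray:
    return np.array([f"rs{j + 1 + offset:06d}" for j in range(J)])


def simulate_mediation(config: ScenarioConfig):
    """Exposure, mediator and outcome tables for a mediation scenario.

    All tables cover the same J + J_med SNPs. Exposure instruments carry
    effects gamma_j on the exposure, a*gamma_j on the mediator and
    (c + a*b)*gamma_j on the outcome; the J_med mediator-specific SNPs
    carry delta_m on the mediator and b*delta_m on the outcome only.
    Returns (exposure, mediator, outcome tables, truth) with the true
    proportion mediated recorded.
    """
    if config.mediation is None:
        raise ConfigurationError("config.mediation block is required")
    med = config.mediation
    rng = np.random.default_rng(config.seed)
    J, Jm = config.J, med.J_med
    Jt = J + Jm

    maf = rng.uniform(*config.maf_range, Jt)
    ea, oa = _assign_alleles(rng, Jt, config.palindromic_rate)
    eaf = np.where(rng.random(Jt) < 0.5, maf, 1.0 - maf)

    se_x = _gwas_se(config.n_exposure, maf)
    se_m = _gwas_se(med.n_mediator, maf)
    se_y = _gwas_se(config.n_outcome, maf)

    z_x = rng.uniform(*config.z_range, J)
    gamma = rng.choice([-1.0, 1.0], J) * z_x * se_x[:J]
    z_m = rng.uniform(*config.z_range, Jm)
    delta = rng.choice([-1.0, 1.0], Jm) * z_m * se_m[J:]

    true_x = np.concatenate([gamma, np.zeros(Jm)])
    true_m = np.concatenate([med.a * gamma, delta])
    true_y = np.concatenate([med.theta_total * gamma, med.b * delta])
    true_y = true_y + config.pleiotropy.draw(rng, true_x, se_y)

    bx = rng.normal(true_x, se_x)
    bm = rng.normal(true_m, se_m)

    ids = _snp_ids(Jt)
    exposure = _make_table("exposure", ids, ea, oa, eaf, bx, se_x, n=config.n_exposure)
    ea_m, oa_m, eaf_m, bm_p = _present_outcome(rng, ea, oa, eaf.copy(), bm)
    mediator = _make_table("mediator", ids, ea_m, oa_m, eaf_m, bm_p, se_m,
                           trait_type="continuous", n=med.n_mediator)
    outcomes = []
    for c in range(config.cohorts):
        by = rng.normal(true_y, se_y)
        eaf_c = np.clip(eaf + rng.normal(0.0, 0.005, Jt), 0.001, 0.999)
        ea_c, oa_c, eaf_c, by_c = _present_outcome(rng, ea, oa, eaf_c, by)
        outcomes.append(
            _make_table(f"outcome_cohort{c + 1}", ids, ea_c, oa_c, eaf_c, by_c,
                        se_y, n=config.n_outcome)
        )
    truth = {
        "a": med.a,
        "b": med.b,
        "c": med.c,
        "theta_total": med.theta_total,
        "true_proportion": med.true_proportion,
        "gamma": gamma,
        "delta": delta,
        "snp_ids": ids,
    }
    return exposure, mediator, outcomes, truth


def simulate_cohort_bundle(
    config: ScenarioConfig,
    out_dir: str | Path,
    n_outcomes: int = 24,
    n_nonzero: int = 12,
    theta_range: tuple[float, float] = (0.18, 0.46),
    write_files: bool = True,
):
    """A full study bundle: 24 outcomes across 2-3 cohorts, mixed truth.

    One shared exposure GWAS; outcomes 1..n_nonzero receive true effects
    drawn uniformly from ``theta_range`` (log-odds, the scale of the
    pooled odds ratios a real study reports), the rest are null. The
    first three outcomes get a third cohort. Writes the summary tables,
    a ``manifest.json``, a ``truth.json`` and a ready-to-run pipeline
    ``config.yaml``; returns the manifest dict.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)

    maf, se_x, gamma, ea, oa, eaf = _draw_instruments(
        rng, config, config.J, config.n_exposure
    )
    bx = rng.normal(gamma, se_x)
    exposure = _make_table("exposure", _snp_ids(config.J), ea, oa, eaf, bx, se_x,
                           n=config.n_exposure)

    n_nonzero = min(n_nonzero, n_outcomes)
    thetas = np.zeros(n_outcomes)
    thetas[:n_nonzero] = rng.uniform(*theta_range, n_nonzero)
    se_y = _gwas_se(config.n_outcome, maf)

    manifest = {"exposure": {"name": "exposure", "file": "exposure.tsv"},
                "outcomes": [], "seed": config.seed}
    tables = {"exposure": exposure}
    for i in range(n_outcomes):
        name = f"outcome{i + 1:02d}"
        n_cohorts = 3 if i < 3 else 2
        alpha = config.pleiotropy.draw(rng, gamma, se_y)
        entry = {"name": name, "cohorts": []}
        for c in range(n_cohorts):
            label = f"cohort{chr(ord('A') + c)}"
            by = rng.normal(thetas[i] * gamma + alpha, se_y)
            eaf_c = np.clip(eaf + rng.normal(0.0, 0.005, config.J), 0.001, 0.999)
            ea_c, oa_c, eaf_c, by_c = _present_outcome(rng, ea, oa, eaf_c, by)
            tab = _make_table(f"{name}_{label}", _snp_ids(config.J), ea_c, oa_c,
                              eaf_c, by_c, se_y, n=config.n_outcome)
            fname = f"{name}_{label}.tsv"
            tables[f"{name}/{label}"] = tab
            entry["cohorts"].append({"label": label, "file": fname})
        manifest["outcomes"].append(entry)

    truth = {"thetas": {f"outcome{i + 1:02d}": float(thetas[i]) for i in range(n_outcomes)}}

    if write_files:
        from .summstats import write_summary_table

        write_summary_table(exposure, out_dir / "exposure.tsv")
        for entry in manifest["outcomes"]:
            for coh in entry["cohorts"]:
                write_summary_table(tables[f"{entry['name']}/{coh['label']}"],
                                    out_dir / coh["file"])
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        _write_run_config(out_dir, manifest)

    return {"manifest": manifest, "truth": truth, "tables": tables, "dir": out_dir}


def _write_run_config(out_dir: Path, manifest: dict) -> None:
    import yaml

    cfg = {
        "exposure": {"name": "exposure", "file": "exposure.tsv"},
        "outcomes": [
            {"name": e["name"],
             "cohorts": [{"label": c["label"], "file": c["file"]} for c in e["cohorts"]]}
            for e in manifest["outcomes"]
        ],
        "thresholds": {"p_instrument": 5e-8, "ld_r2": 0.01, "alpha": 0.05},
        "estimators": {"n_boot": 1000, "presso_k": 1000, "seed": int(manifest["seed"])},
        "output_dir": "results",
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
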