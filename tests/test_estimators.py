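"""Univariable estimators against independent normal-equations oracles."""

import numpy as np
import pytest
from scipy import stats

from mrkit import (
    HarmonizedSet,
    cochran_q,
    ivw,
    mr_egger,
    mr_presso,
    ratio_estimates,
    to_odds_ratio,
    weighted_median,
)
from mrkit.errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)

from conftest import random_harmonized_set


def oracle_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Independent weighted normal equations: (X'WX)^-1 X'Wy."""
    Xw = X * w[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T @ y)


class TestRatio:
    def test_arithmetic_and_signs(self):
        hs = HarmonizedSet.from_arrays(
            bx=[0.1, -0.2], se_x=[0.01, 0.01], by=[0.05, 0.05], se_y=[0.01, 0.01]
        )
        b, s = ratio_estimates(hs)
        np.testing.assert_allclose(b, [0.5, -0.25])
        np.testing.assert_allclose(s, [0.1, 0.05])

    def test_null_outcome_gives_zero_ratios(self):
        hs = HarmonizedSet.from_arrays(
            bx=[0.1, 0.2, 0.3], se_x=[0.01] * 3, by=[0.0] * 3, se_y=[0.01] * 3
        )
        assert np.all(ratio_estimates(hs)[0] == 0)

    def test_zero_exposure_beta_names_the_snp(self):
        hs = HarmonizedSet.from_arrays(
            bx=[0.1, 0.0], se_x=[0.01] * 2, by=[0.05, 0.05], se_y=[0.01] * 2,
            snp_ids=["rs1", "rs2"],
        )
        with pytest.raises(DegenerateInstrumentError, match="rs2"):
            ratio_estimates(hs)


class TestIVW:
    def test_toy_closed_form(self, toy_set):
        est = ivw(toy_set)
        assert est.beta == pytest.approx(330 / 725, abs=1e-12)
        assert est.nsnp == 3

    def test_exact_fit_recovers_theta_with_floored_dispersion(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        hs = HarmonizedSet.from_arrays(
            bx=bx, se_x=[0.01] * 4, by=0.3 * bx, se_y=[0.01] * 4
        )
        est = ivw(hs)
        assert est.beta == pytest.approx(0.3, abs=1e-14)
        # phi floored at 1: SE equals the fixed-effect SE
        w = np.full(4, 0.01) ** -2.0
        assert est.se == pytest.approx(np.sqrt(1 / np.sum(w * bx**2)), abs=1e-14)

    def test_single_snp_reduces_to_wald_ratio(self):
        hs = HarmonizedSet.from_arrays(bx=[0.1], se_x=[0.01], by=[0.05], se_y=[0.01])
        est = ivw(hs)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_matches_normal_equations_oracle_on_random_sets(self, rng):
        for _ in range(50):
            hs = random_harmonized_set(rng, J=int(rng.integers(5, 40)))
            est = ivw(hs)
            w = hs.se_y**-2.0
            expected = oracle_wls(hs.bx[:, None], hs.by, w)[0]
            assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_random_effects_se_never_below_fixed_effect_se(self, rng):
        for _ in range(20):
            hs = random_harmonized_set(rng)
            w = hs.se_y**-2.0
            fixed = np.sqrt(1 / np.sum(w * hs.bx**2))
            assert ivw(hs).se >= fixed - 1e-15

    def test_ci_follows_the_normal_convention(self, toy_set):
        est = ivw(toy_set)
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)


class TestCochranQ:
    def test_exact_fit_has_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = HarmonizedSet.from_arrays(bx=bx, se_x=[0.01] * 3, by=0.3 * bx,
                                       se_y=[0.01] * 3)
        q, df, p = cochran_q(hs, ivw(hs))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_matches_direct_summation(self, toy_set):
        est = ivw(toy_set)
        q, df, p = cochran_q(toy_set, est)
        w = toy_set.se_y**-2.0
        q_direct = float(np.sum(w * (toy_set.by - est.beta * toy_set.bx) ** 2))
        assert q == pytest.approx(q_direct, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(q_direct, 2), abs=1e-12)

    def test_duplicating_instruments_doubles_q(self, toy_set):
        est = ivw(toy_set)
        q1, _, _ = cochran_q(toy_set, est)
        dup = HarmonizedSet.from_arrays(
            bx=np.tile(toy_set.bx, 2), se_x=np.tile(toy_set.se_x, 2),
            by=np.tile(toy_set.by, 2), se_y=np.tile(toy_set.se_y, 2),
        )
        q2, _, _ = cochran_q(dup, est.beta)
        assert q2 == pytest.approx(2 * q1, abs=1e-12)

    def test_needs_two_instruments(self):
        hs = HarmonizedSet.from_arrays(bx=[0.1], se_x=[0.01], by=[0.05], se_y=[0.01])
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(hs, 0.3)


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        hs = HarmonizedSet.from_arrays(
            bx=bx, se_x=[0.01] * 5, by=0.02 + 0.3 * bx, se_y=[0.01] * 5
        )
        slope, intercept = mr_egger(hs)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.02, abs=1e-12)

    def test_orientation_invariance(self, rng):
        hs = random_harmonized_set(rng, J=8)
        s1, i1 = mr_egger(hs)
        flipped = HarmonizedSet.from_arrays(
            bx=-hs.bx, se_x=hs.se_x, by=-hs.by, se_y=hs.se_y
        )
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)
        assert s1.se == pytest.approx(s2.se, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            hs = random_harmonized_set(rng, J=int(rng.integers(5, 30)))
            slope, intercept = mr_egger(hs)
            sgn = np.where(hs.bx < 0, -1.0, 1.0)
            bx, by = sgn * hs.bx, sgn * hs.by
            w = hs.se_y**-2.0
            X = np.column_stack([np.ones_like(bx), bx])
            b0, b1 = oracle_wls(X, by, w)
            assert intercept.beta == pytest.approx(b0, abs=1e-10)
            assert slope.beta == pytest.approx(b1, abs=1e-10)
            # dispersion-floored SEs from the same normal equations
            resid = by - X @ np.array([b0, b1])
            phi = max(1.0, float(np.sum(w * resid**2) / (len(bx) - 2)))
            cov = phi * np.linalg.inv(X.T @ (X * w[:, None]))
            assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
            assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_interpolates_the_middle_ratio(self):
        hs = HarmonizedSet.from_arrays(
            bx=[1.0, 1.0, 1.0], se_x=[0.01] * 3, by=[0.2, 0.5, 0.9], se_y=[0.1] * 3
        )
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_constant_ratios_give_tiny_bootstrap_se(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hs = HarmonizedSet.from_arrays(
            bx=bx, se_x=[1e-6] * 4, by=0.4 * bx, se_y=[1e-6] * 4
        )
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-6)
        assert est.se < 1e-4

    def test_seeded_determinism(self, rng):
        hs = random_harmonized_set(rng)
        a = weighted_median(hs, n_boot=300, seed=42)
        b = weighted_median(hs, n_boot=300, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(20):
            hs = random_harmonized_set(rng, J=int(rng.integers(3, 25)))
            ratios = hs.by / hs.bx
            est = weighted_median(hs, n_boot=10, seed=0)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


class TestPresso:
    def test_clean_data_rarely_flags_outliers(self):
        from mrkit import ScenarioConfig, simulate_two_sample, select_instruments, harmonize

        clean_runs = 0
        n_runs = 30
        for s in range(n_runs):
            exp, outs, _ = simulate_two_sample(ScenarioConfig(seed=1000 + s, cohorts=1))
            hs = harmonize(select_instruments(exp), outs[0])
            rep = mr_presso(hs, K=300, seed=s)
            clean_runs += not rep.outlier_snps
        assert clean_runs >= int(0.9 * n_runs)

    def test_planted_outlier_flagged_and_correction_helps(self, rng):
        theta = 0.3
        J = 30
        bx = rng.uniform(0.02, 0.06, J)
        se_y = np.full(J, 0.004)
        by = theta * bx + rng.normal(0, se_y)
        by[7] += 10 * se_y[7]
        hs = HarmonizedSet.from_arrays(
            bx=bx, se_x=np.full(J, 0.002), by=by, se_y=se_y,
            snp_ids=np.array([f"rs{i}" for i in range(J)]),
        )
        rep = mr_presso(hs, K=500, seed=3)
        assert "rs7" in rep.outlier_snps
        assert abs(rep.corrected.beta - theta) < abs(rep.raw.beta - theta)
        assert rep.corrected.nsnp == rep.raw.nsnp - len(rep.outlier_snps)
        assert rep.distortion_p is not None

    def test_global_p_bounds_and_determinism(self, rng):
        hs = random_harmonized_set(rng, J=12)
        a = mr_presso(hs, K=200, seed=9)
        b = mr_presso(hs, K=200, seed=9)
        assert a.global_p == b.global_p
        assert 1 / 201 <= a.global_p <= 1.0

    def test_minimum_instruments_enforced(self, rng):
        hs = random_harmonized_set(rng, J=3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(hs, K=100, seed=0)


class TestOddsRatio:
    def test_closed_form_at_null(self):
        from mrkit import MREstimate

        est = MREstimate.from_beta_se("ivw", 0.0, 0.1, 5)
        or_, lo, hi = to_odds_ratio(est)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-0.196), abs=1e-12)
        assert hi == pytest.approx(np.exp(0.196), abs=1e-12)

    def test_degenerate_zero_se(self):
        from mrkit import MREstimate

        est = MREstimate.from_beta_se("ivw", 0.0, 0.0, 5)
        assert to_odds_ratio(est) == (1.0, 1.0, 1.0)

    def test_monotone_in_beta_and_width_grows_with_se(self):
        from mrkit import MREstimate

        ors = [to_odds_ratio(MREstimate.from_beta_se("ivw", b, 0.1, 5))[0]
               for b in (-0.2, 0.0, 0.3)]
        assert ors == sorted(ors)
        w1 = np.subtract(*to_odds_ratio(MREstimate.from_beta_se("ivw", 0.1, 0.05, 5))[:0:-1])
        w2 = np.subtract(*to_odds_ratio(MREstimate.from_beta_se("ivw", 0.1, 0.2, 5))[:0:-1])
        assert w2 > w1
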