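"""Multivariable MR and the two-step mediation decomposition."""

import numpy as np
import pytest

from mrkit import (
    HarmonizedSet,
    MVMRInput,
    ScenarioConfig,
    MediationDesign,
    build_mvmr_input,
    combined_mediation,
    harmonize,
    ivw,
    mediation_analysis,
    mvmr_fit,
    select_instruments,
    simulate_mediation,
)
from mrkit.errors import CollinearityError, NotEstimableError

from conftest import random_harmonized_set


def _mvin_from_hs(hs, extra_cols=None, names=("x",)):
    bx = hs.bx[:, None] if extra_cols is None else np.column_stack([hs.bx] + extra_cols)
    se = np.full_like(bx, 0.005)
    return MVMRInput(
        snp_ids=hs.snp_ids, exposure_names=tuple(names), bx=bx, se_x=se,
        by=hs.by, se_y=hs.se_y,
    )


class TestMVMRFit:
    def test_single_column_reduces_to_ivw(self, rng):
        for _ in range(10):
            hs = random_harmonized_set(rng, J=15)
            fit = mvmr_fit(_mvin_from_hs(hs))[0]
            est = ivw(hs)
            assert fit.beta == pytest.approx(est.beta, abs=1e-10)
            assert fit.se == pytest.approx(est.se, abs=1e-10)

    def test_orthogonal_columns_decouple(self, rng):
        # two exposures whose weighted cross-product is exactly zero
        J = 20
        se_y = np.full(J, 0.01)
        w = se_y**-2.0
        x1 = rng.normal(0, 0.05, J)
        x2 = rng.normal(0, 0.05, J)
        x2 -= x1 * np.sum(w * x1 * x2) / np.sum(w * x1 * x1)  # orthogonalise
        by = 0.2 * x1 + 0.4 * x2 + rng.normal(0, 0.005, J)
        mvin = MVMRInput(
            snp_ids=np.array([f"rs{i}" for i in range(J)]),
            exposure_names=("x1", "x2"),
            bx=np.column_stack([x1, x2]), se_x=np.full((J, 2), 0.005),
            by=by, se_y=se_y,
        )
        joint = mvmr_fit(mvin)
        uni1 = ivw(HarmonizedSet.from_arrays(bx=x1, se_x=np.full(J, 0.005), by=by, se_y=se_y))
        uni2 = ivw(HarmonizedSet.from_arrays(bx=x2, se_x=np.full(J, 0.005), by=by, se_y=se_y))
        assert joint[0].beta == pytest.approx(uni1.beta, abs=1e-10)
        assert joint[1].beta == pytest.approx(uni2.beta, abs=1e-10)

    def test_exact_two_exposure_fit(self, rng):
        J = 12
        x1 = rng.uniform(0.01, 0.08, J)
        x2 = rng.uniform(-0.05, 0.05, J)
        mvin = MVMRInput(
            snp_ids=np.array([f"rs{i}" for i in range(J)]),
            exposure_names=("x1", "x2"),
            bx=np.column_stack([x1, x2]), se_x=np.full((J, 2), 0.005),
            by=0.2 * x1 + 0.4 * x2, se_y=np.full(J, 0.01),
        )
        fit = mvmr_fit(mvin)
        assert fit[0].beta == pytest.approx(0.2, abs=1e-12)
        assert fit[1].beta == pytest.approx(0.4, abs=1e-12)

    def test_collinear_columns_rejected(self, rng):
        J = 10
        x1 = rng.uniform(0.01, 0.08, J)
        mvin = MVMRInput(
            snp_ids=np.array([f"rs{i}" for i in range(J)]),
            exposure_names=("x1", "x2"),
            bx=np.column_stack([x1, 2 * x1]), se_x=np.full((J, 2), 0.005),
            by=0.2 * x1, se_y=np.full(J, 0.01),
        )
        with pytest.raises(CollinearityError):
            mvmr_fit(mvin)

    def test_matches_normal_equations_oracle(self, rng):
        from conftest import random_harmonized_set

        for _ in range(10):
            J = 25
            X = rng.normal(0, 0.05, (J, 3))
            se_y = rng.uniform(0.005, 0.02, J)
            by = X @ np.array([0.2, -0.1, 0.4]) + rng.normal(0, se_y)
            mvin = MVMRInput(
                snp_ids=np.array([f"rs{i}" for i in range(J)]),
                exposure_names=("a", "b", "c"),
                bx=X, se_x=np.full((J, 3), 0.005), by=by, se_y=se_y,
            )
            fit = mvmr_fit(mvin)
            w = se_y**-2.0
            expected = np.linalg.solve(X.T @ (X * w[:, None]), (X * w[:, None]).T @ by)
            for f, e in zip(fit, expected):
                assert f.beta == pytest.approx(e, abs=1e-10)


def _mediation_setup(seed, a=0.2, b=0.5, c=0.1):
    cfg = ScenarioConfig(seed=seed, cohorts=1,
                         mediation=MediationDesign(a=a, b=b, c=c))
    exp, med, outs, truth = simulate_mediation(cfg)
    instr = select_instruments(exp)
    hs_xy = harmonize(instr, outs[0])
    hs_xm = harmonize(instr, med)
    mvin = build_mvmr_input([("exposure", exp), ("mediator", med)], outs[0])
    return hs_xy, hs_xm, mvin, truth


class TestMediation:
    def test_product_rule_arithmetic(self):
        """total 0.4, alpha 0.5, beta_med 0.4 -> indirect 0.2, proportion 50%."""
        from mrkit import MREstimate
        from mrkit.mediation import MediationResult

        res = MediationResult(
            outcome_name="y", mediators=("m",),
            total=MREstimate.from_beta_se("ivw", 0.4, 0.05, 10),
            alpha=(MREstimate.from_beta_se("ivw", 0.5, 0.05, 10),),
            beta_med=(MREstimate.from_beta_se("mvmr", 0.4, 0.05, 10),),
            direct=MREstimate.from_beta_se("mvmr", 0.2, 0.05, 10),
            indirect_beta=0.5 * 0.4, indirect_se=None,
        )
        assert res.proportion_mediated == pytest.approx(0.5)

    def test_pipeline_recovers_true_proportion(self):
        hs_xy, hs_xm, mvin, truth = _mediation_setup(seed=21)
        res = mediation_analysis(hs_xy, hs_xm, mvin)
        assert truth["true_proportion"] == pytest.approx(0.5)
        assert res.proportion_mediated == pytest.approx(0.5, abs=0.15)
        assert res.indirect_beta == pytest.approx(
            res.alpha[0].beta * res.beta_med[0].beta
        )

    def test_null_path_centres_on_zero(self):
        props = []
        for s in range(10):
            hs_xy, hs_xm, mvin, _ = _mediation_setup(seed=100 + s, a=0.0, c=0.2)
            props.append(mediation_analysis(hs_xy, hs_xm, mvin).proportion_mediated)
        assert abs(np.mean(props)) < 0.05

    def test_zero_total_effect_not_estimable(self, rng):
        from mrkit import MREstimate
        from mrkit.mediation import MediationResult

        with pytest.raises(NotEstimableError):
            MediationResult(
                outcome_name="y", mediators=("m",),
                total=MREstimate("ivw", 0.0, 0.1, -0.196, 0.196, 1.0, 10),
                alpha=(MREstimate.from_beta_se("ivw", 0.5, 0.05, 10),),
                beta_med=(MREstimate.from_beta_se("mvmr", 0.4, 0.05, 10),),
                direct=MREstimate.from_beta_se("mvmr", 0.2, 0.05, 10),
                indirect_beta=0.2, indirect_se=None,
            )

    def test_negative_proportion_passes_unclamped(self):
        from mrkit import MREstimate
        from mrkit.mediation import MediationResult

        res = MediationResult(
            outcome_name="y", mediators=("m",),
            total=MREstimate.from_beta_se("ivw", 0.4, 0.05, 10),
            alpha=(MREstimate.from_beta_se("ivw", -0.1, 0.05, 10),),
            beta_med=(MREstimate.from_beta_se("mvmr", 0.2, 0.05, 10),),
            direct=MREstimate.from_beta_se("mvmr", 0.42, 0.05, 10),
            indirect_beta=-0.02, indirect_se=None,
        )
        assert res.proportion_mediated == pytest.approx(-0.05)

    def test_proportion_scale_invariant_in_outcome_units(self):
        hs_xy, hs_xm, mvin, _ = _mediation_setup(seed=33)
        res1 = mediation_analysis(hs_xy, hs_xm, mvin)
        scale = 3.0
        hs_xy2 = HarmonizedSet.from_arrays(
            bx=hs_xy.bx, se_x=hs_xy.se_x, by=scale * hs_xy.by,
            se_y=scale * hs_xy.se_y, snp_ids=hs_xy.snp_ids,
        )
        mvin2 = MVMRInput(
            snp_ids=mvin.snp_ids, exposure_names=mvin.exposure_names,
            bx=mvin.bx, se_x=mvin.se_x, by=scale * mvin.by, se_y=scale * mvin.se_y,
        )
        res2 = mediation_analysis(hs_xy2, hs_xm, mvin2)
        assert res2.proportion_mediated == pytest.approx(
            res1.proportion_mediated, abs=1e-10
        )


class TestCombinedMediation:
    def test_single_mediator_reduces_to_mediation_analysis(self):
        hs_xy, hs_xm, mvin, _ = _mediation_setup(seed=55)
        single = mediation_analysis(hs_xy, hs_xm, mvin)
        combined = combined_mediation(hs_xy, [ivw(hs_xm)], mvin)
        assert combined.indirect_beta == pytest.approx(single.indirect_beta, abs=1e-12)
        assert combined.proportion_mediated == pytest.approx(
            single.proportion_mediated, abs=1e-12
        )

    def test_null_second_path_adds_nothing(self, rng):
        J = 30
        x = rng.uniform(0.02, 0.08, J)
        m1 = 0.5 * x + rng.normal(0, 0.002, J)
        m2 = rng.normal(0, 0.03, J)  # unrelated to outcome
        by = 0.1 * x + 0.4 * m1 + rng.normal(0, 0.004, J)
        ids = np.array([f"rs{i}" for i in range(J)])
        se_y = np.full(J, 0.004)
        hs_xy = HarmonizedSet.from_arrays(bx=x, se_x=np.full(J, 0.002), by=by,
                                          se_y=se_y, snp_ids=ids)
        a1 = ivw(HarmonizedSet.from_arrays(bx=x, se_x=np.full(J, 0.002), by=m1,
                                           se_y=np.full(J, 0.002), snp_ids=ids))
        a2 = ivw(HarmonizedSet.from_arrays(bx=x, se_x=np.full(J, 0.002), by=m2,
                                           se_y=np.full(J, 0.03), snp_ids=ids))
        mv2 = MVMRInput(snp_ids=ids, exposure_names=("x", "m1"),
                        bx=np.column_stack([x, m1]), se_x=np.full((J, 2), 0.002),
                        by=by, se_y=se_y)
        mv3 = MVMRInput(snp_ids=ids, exposure_names=("x", "m1", "m2"),
                        bx=np.column_stack([x, m1, m2]), se_x=np.full((J, 3), 0.002),
                        by=by, se_y=se_y)
        single = combined_mediation(hs_xy, [a1], mv2)
        both = combined_mediation(hs_xy, [a1, a2], mv3)
        assert both.proportion_mediated == pytest.approx(
            single.proportion_mediated, abs=0.05
        )
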