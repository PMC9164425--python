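"""Structural-model unit tests: conditional means, log density, serialisation."""

import io

import numpy as np
import pytest
from scipy import stats

from bayesmr import (
    CombinedDataset,
    InstrumentLayout,
    PriorSpec,
    StructuralParams,
    StudyDataset,
    conditional_means,
    log_joint,
)
from bayesmr.mr_model import combined_to_frame, frame_to_combined


def _zero_params(layout: InstrumentLayout, **overrides) -> StructuralParams:
    p = StructuralParams.homogeneous(layout, alpha=0.0, beta=0.0, delta=0.0, sigma=1.0)
    return p.with_(**overrides)


def _tiny_study(layout: InstrumentLayout, study: str, n: int, rng, with_x=True) -> StudyDataset:
    z = lambda m: rng.integers(0, 3, size=(n, m)).astype(float)
    kw = dict(X1=rng.normal(size=n), X2=rng.normal(size=n)) if with_x else {}
    return StudyDataset(
        study=study, Z1=z(layout.L), Z2=z(layout.K), Z3=z(layout.M),
        Y1=rng.normal(size=n), Y2=rng.normal(size=n), **kw,
    )


class TestConditionalMeans:
    def test_all_zero_params_give_zero_means(self, small_layout, rng):
        ds = _tiny_study(small_layout, "A", 5, rng)
        params = _zero_params(small_layout)
        for m in conditional_means(params, ds, np.zeros(5)):
            assert np.all(m == 0.0)

    def test_study_b_intercept_only(self, small_layout, rng):
        ds = _tiny_study(small_layout, "B", 4, rng, with_x=False)
        params = _zero_params(small_layout, v_x1=0.4)
        m_x1, m_x2, _, _ = conditional_means(
            params, ds, np.zeros(4), X1=np.zeros(4), X2=np.zeros(4)
        )
        assert np.allclose(m_x1, 0.4)
        assert np.allclose(m_x2, 0.0)

    def test_hand_computed_dot_product(self):
        # one individual, Z1 all ones with alpha1 = 0.3 (L=15), Z3 contribution
        # zeroed, delta_x1 = 1, U = 0.5: mean(X1) = 15*0.3 + 0.5 = 5.0
        layout = InstrumentLayout(15, 2, 3)
        params = _zero_params(layout, delta_x1=1.0).with_(alpha1=np.full(15, 0.3))
        ds = StudyDataset(
            study="A",
            Z1=np.ones((1, 15)), Z2=np.zeros((1, 2)), Z3=np.zeros((1, 3)),
            X1=np.zeros(1), X2=np.zeros(1), Y1=np.zeros(1), Y2=np.zeros(1),
        )
        m_x1, *_ = conditional_means(params, ds, np.array([0.5]))
        assert m_x1[0] == pytest.approx(5.0)

    def test_study_a_equals_study_b_with_zero_v(self, small_layout, small_params, rng):
        ds_a = _tiny_study(small_layout, "A", 6, rng)
        ds_b = StudyDataset(
            study="B", Z1=ds_a.Z1, Z2=ds_a.Z2, Z3=ds_a.Z3, Y1=ds_a.Y1, Y2=ds_a.Y2
        )
        U = rng.normal(size=6)
        means_a = conditional_means(small_params, ds_a, U)
        means_b = conditional_means(small_params, ds_b, U, X1=ds_a.X1, X2=ds_a.X2)
        for ma, mb in zip(means_a, means_b):
            np.testing.assert_array_equal(ma, mb)

    def test_dimension_mismatch_raises(self, small_layout, small_params, rng):
        ds = _tiny_study(small_layout, "A", 5, rng)
        with pytest.raises(ValueError, match="shape"):
            conditional_means(small_params, ds, np.zeros(4))
        wrong = StructuralParams.homogeneous(InstrumentLayout(2, 3, 2))
        with pytest.raises(ValueError, match="layout"):
            conditional_means(wrong, ds, np.zeros(5))


class TestLogJoint:
    def test_standard_normal_at_zero(self, small_layout):
        # all observations and params zero, sigmas 1: data part is five
        # standard-normal densities at zero per individual (U + 4 regressions)
        params = _zero_params(small_layout)
        ds = StudyDataset(
            study="A",
            Z1=np.zeros((1, 3)), Z2=np.zeros((1, 3)), Z3=np.zeros((1, 2)),
            X1=np.zeros(1), X2=np.zeros(1), Y1=np.zeros(1), Y2=np.zeros(1),
        )
        val = log_joint(params, ds, np.zeros(1), PriorSpec(), include_priors=False)
        assert val == pytest.approx(5 * (-0.5 * np.log(2 * np.pi)))

    def test_matches_scipy_normal_logpdfs(self, small_layout, small_params, rng):
        ds = _tiny_study(small_layout, "B", 3, rng, with_x=False)
        params = small_params.with_(v_x1=0.2, v_x2=-0.1, v_y1=0.3, v_y2=0.05)
        U = rng.normal(size=3)
        X1 = rng.normal(size=3)
        X2 = rng.normal(size=3)
        m = conditional_means(params, ds, U, X1=X1, X2=X2)
        expected = stats.norm.logpdf(U).sum()
        for obs, mean, sd in zip(
            (X1, X2, ds.Y1, ds.Y2), m, params.sigmas("B")
        ):
            expected += stats.norm.logpdf(obs, loc=mean, scale=sd).sum()
        got = log_joint(params, ds, U, PriorSpec(), X1=X1, X2=X2, include_priors=False)
        assert got == pytest.approx(expected)

    def test_decreases_with_outcome_residual(self, small_layout, small_params, rng):
        ds = _tiny_study(small_layout, "A", 4, rng)
        U = rng.normal(size=4)
        pr = PriorSpec()
        base = log_joint(small_params, ds, U, pr)
        worse = StudyDataset(
            study="A", Z1=ds.Z1, Z2=ds.Z2, Z3=ds.Z3,
            X1=ds.X1, X2=ds.X2, Y1=ds.Y1 + 5.0, Y2=ds.Y2,
        )
        assert log_joint(small_params, worse, U, pr) < base

    def test_symmetry_under_pair_swap(self, rng):
        # swapping (X1,Y1,Z1,alpha1,beta1,...) with (X2,Y2,Z2,alpha2,beta2,...)
        # and alpha31 with alpha32 leaves the joint density unchanged
        layout = InstrumentLayout(3, 3, 2)
        params = StructuralParams(
            alpha1=rng.normal(size=3), alpha2=rng.normal(size=3),
            alpha31=rng.normal(size=2), alpha32=rng.normal(size=2),
            beta1=0.4, beta2=-0.2, delta_x1=0.9, delta_x2=1.2,
            delta_y1=0.7, delta_y2=1.1,
            sigma_x1a=0.3, sigma_x2a=0.5, sigma_y1a=0.2, sigma_y2a=0.4,
        )
        ds = _tiny_study(layout, "A", 5, rng)
        U = rng.normal(size=5)
        pr = PriorSpec()
        swapped_params = StructuralParams(
            alpha1=params.alpha2, alpha2=params.alpha1,
            alpha31=params.alpha32, alpha32=params.alpha31,
            beta1=params.beta2, beta2=params.beta1,
            delta_x1=params.delta_x2, delta_x2=params.delta_x1,
            delta_y1=params.delta_y2, delta_y2=params.delta_y1,
            sigma_x1a=params.sigma_x2a, sigma_x2a=params.sigma_x1a,
            sigma_y1a=params.sigma_y2a, sigma_y2a=params.sigma_y1a,
        )
        swapped_ds = StudyDataset(
            study="A", Z1=ds.Z2, Z2=ds.Z1, Z3=ds.Z3,
            X1=ds.X2, X2=ds.X1, Y1=ds.Y2, Y2=ds.Y1,
        )
        assert log_joint(params, ds, U, pr) == pytest.approx(
            log_joint(swapped_params, swapped_ds, U, pr)
        )

    def test_additive_over_individuals(self, small_layout, small_params, rng):
        ds = _tiny_study(small_layout, "A", 4, rng)
        U = rng.normal(size=4)
        pr = PriorSpec()
        full = log_joint(small_params, ds, U, pr, include_priors=False)
        parts = sum(
            log_joint(
                small_params, ds.take(np.array([i])), U[i : i + 1], pr,
                include_priors=False,
            )
            for i in range(4)
        )
        assert full == pytest.approx(parts)

    def test_nonpositive_sigma_rejected(self, small_layout):
        with pytest.raises(ValueError, match="positive"):
            _zero_params(small_layout, sigma_y1a=0.0)


class TestDatasetValidation:
    def test_dosages_outside_012_rejected(self, small_layout):
        with pytest.raises(ValueError, match="dosage"):
            StudyDataset(
                study="A",
                Z1=np.full((2, 3), 3.0), Z2=np.zeros((2, 3)), Z3=np.zeros((2, 2)),
                X1=np.zeros(2), X2=np.zeros(2), Y1=np.zeros(2), Y2=np.zeros(2),
            )

    def test_partial_exposures_rejected(self, small_layout, rng):
        with pytest.raises(ValueError, match="both"):
            StudyDataset(
                study="A",
                Z1=np.zeros((2, 3)), Z2=np.zeros((2, 3)), Z3=np.zeros((2, 2)),
                X1=np.zeros(2), X2=None, Y1=np.zeros(2), Y2=np.zeros(2),
            )

    def test_combined_requires_exposure_pattern(self, small_layout, rng):
        a = _tiny_study(small_layout, "A", 3, rng)
        b = _tiny_study(small_layout, "B", 2, rng, with_x=False)
        combined = CombinedDataset(study_a=a, study_b=b)
        assert combined.missing_rate == pytest.approx(2 / 5)
        with pytest.raises(ValueError, match="absent"):
            CombinedDataset(study_a=a, study_b=a)


class TestSerialisation:
    def test_round_trip_through_csv(self, default_combined):
        combined, _ = default_combined
        buf = io.StringIO()
        combined_to_frame(combined).to_csv(buf, index=False)
        buf.seek(0)
        import pandas as pd

        back = frame_to_combined(pd.read_csv(buf))
        np.testing.assert_allclose(back.study_a.X1, combined.study_a.X1)
        np.testing.assert_array_equal(back.study_b.Z3, combined.study_b.Z3)
        assert back.study_b.X1 is None
        assert back.missing_rate == combined.missing_rate

    def test_priors_yaml_round_trip(self, tmp_path):
        pr = PriorSpec(alpha_sd=0.25, delta_sd=2.0)
        path = str(tmp_path / "priors.yaml")
        pr.to_yaml(path)
        assert PriorSpec.from_yaml(path) == pr
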