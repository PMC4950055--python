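"""Penalized-likelihood LMS fitting: recovery, oracles, diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize

import lmsgrowth as lg
from lmsgrowth._splines import (
    SingularBasisError,
    SplineBasis,
    difference_penalty,
    edf_for_lambda,
    lambda_for_edf,
)
from lmsgrowth.model import FitConfig, InsufficientDataError, LMSModel


def _simulate_constant(rng, n, L, M, S, weeks=(28, 43)):
    z = rng.standard_normal(n)
    keep = 1.0 + L * S * z > 0
    z = z[keep]
    y = M * (1.0 + L * S * z) ** (1.0 / L) if abs(L) > 1e-8 else M * np.exp(S * z)
    t = rng.integers(weeks[0], weeks[1] + 1, z.size).astype(float)
    return y, t


class TestSplineMachinery:
    def test_edf_decreases_with_penalty(self):
        basis = SplineBasis(28, 43)
        B = basis.design(np.arange(28.0, 44.0))
        btwb = B.T @ (np.repeat(50.0, 16)[:, None] * B)
        P = difference_penalty(basis.k)
        edfs = [edf_for_lambda(btwb, P, lam) for lam in (1e-3, 1.0, 1e3, 1e9)]
        assert all(a > b for a, b in zip(edfs, edfs[1:]))
        assert edfs[-1] == pytest.approx(2.0, abs=1e-3)  # linear null space

    def test_lambda_bisection_hits_target(self):
        basis = SplineBasis(28, 43)
        B = basis.design(np.arange(28.0, 44.0))
        btwb = B.T @ B * 100.0
        P = difference_penalty(basis.k)
        lam = lambda_for_edf(btwb, P, 5.0)
        assert edf_for_lambda(btwb, P, lam) == pytest.approx(5.0, abs=2e-3)

    def test_unattainable_edf_raises(self):
        with pytest.raises(SingularBasisError):
            SplineBasis(30, 31)
        basis = SplineBasis(28, 43)
        B = basis.design(np.arange(28.0, 44.0))
        P = difference_penalty(basis.k)
        with pytest.raises(SingularBasisError):
            lambda_for_edf(B.T @ B, P, 30.0)


class TestConstantCurveFits:
    def test_recovers_known_constant_triple(self):
        rng = np.random.default_rng(11)
        y, t = _simulate_constant(rng, 5000, L=1.0, M=3000.0, S=0.15)
        cfg = FitConfig(edf_L=1, edf_M=1, edf_S=1, sex_offset=False)
        res = LMSModel(y, t, config=cfg).fit()
        trip = res.triple("M", 35)
        assert trip.M == pytest.approx(3000.0, rel=0.01)
        assert trip.S == pytest.approx(0.15, rel=0.05)
        assert abs(trip.L - 1.0) < 0.3

    def test_agrees_with_direct_ml_oracle(self):
        # independent oracle: Nelder-Mead on the 3-parameter BCCG likelihood
        rng = np.random.default_rng(42)
        y, t = _simulate_constant(rng, 5000, L=1.0, M=3000.0, S=0.15)
        cfg = FitConfig(
            edf_L=1, edf_M=1, edf_S=1, sex_offset=False, tolerance=1e-11, max_iterations=2000
        )
        res = LMSModel(y, t, config=cfg).fit()

        def negll(p):
            L, logM, logS = p
            mu, sig = np.exp(logM), np.exp(logS)
            s = np.log(y / mu)
            zz = s / sig if abs(L) < 1e-8 else np.expm1(L * s) / (L * sig)
            return -np.sum(L * s - np.log(sig) - zz * zz / 2)

        opt = minimize(
            negll,
            [0.5, np.log(3100.0), np.log(0.2)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        L, M, S = opt.x[0], np.exp(opt.x[1]), np.exp(opt.x[2])
        trip = res.triple("M", 35)
        assert trip.L == pytest.approx(L, abs=1e-3)
        assert trip.M == pytest.approx(M, rel=1e-3)
        assert trip.S == pytest.approx(S, abs=1e-3)

    def test_null_sex_offset_within_noise(self):
        rng = np.random.default_rng(3)
        y, t = _simulate_constant(rng, 6000, L=1.0, M=3000.0, S=0.15)
        sex = np.where(np.arange(y.size) % 2 == 0, "M", "F")
        cfg = FitConfig(edf_L=1, edf_M=1, edf_S=1)
        res = LMSModel(y, t, sex=sex, config=cfg).fit()
        assert abs(res.delta) < 3.0 * res.delta_se


class TestFullRegisterFit:
    def test_penalized_loglik_monotone_across_iterations(self, fit0):
        assert np.all(np.diff(fit0.trace) >= -1e-6 * (np.abs(fit0.trace[:-1]) + 1.0))
        assert fit0.converged

    def test_training_zscores_standard_normal(self, fit0):
        assert abs(fit0.zscores.mean()) < 0.05
        assert abs(fit0.zscores.std(ddof=1) - 1.0) < 0.05

    def test_sex_difference_transform_and_interval(self, fit0):
        sd = fit0.sex_difference_percent()
        assert sd.percent == pytest.approx(100.0 * (1.0 - np.exp(fit0.delta)))
        assert sd.ci_lower < sd.percent < sd.ci_upper
        # interval width comparable to the scale's published-style span (~1.4 pp)
        assert 0.5 < sd.ci_upper - sd.ci_lower < 3.0

    def test_report_window_shape(self, fit0):
        table = fit0.lms_table()
        assert table.week_range == (30, 42)
        frame = table.to_frame()
        assert (frame.groupby("sex").size() == 13).all()

    def test_l_and_s_pooled_across_sexes(self, fit0):
        table = fit0.lms_table(round_params=False)
        for week in table.weeks:
            m, f = table.triple("M", week), table.triple("F", week)
            assert m.L == pytest.approx(f.L)
            assert m.S == pytest.approx(f.S)
            assert f.M / m.M == pytest.approx(np.exp(fit0.delta), rel=1e-12)

    def test_evaluation_outside_fit_window_raises(self, fit0):
        with pytest.raises(ValueError):
            fit0.curves_at([27.0])
        with pytest.raises(ValueError):
            fit0.lms_table(weeks=range(27, 44))

    def test_summary_mentions_key_quantities(self, fit0):
        text = fit0.summary()
        assert "converged" in text and "sex offset" in text and "edf" in text


class TestValidation:
    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            LMSModel(np.full(30, 3000.0), np.full(30, 38.0), config=FitConfig(sex_offset=False))

    def test_sex_offset_requires_both_sexes(self):
        y = np.full(100, 3000.0)
        with pytest.raises(InsufficientDataError):
            LMSModel(y, np.full(100, 38.0), sex=np.repeat("M", 100))

    def test_out_of_window_records_are_excluded_not_clamped(self):
        rng = np.random.default_rng(5)
        y, t = _simulate_constant(rng, 2000, L=1.0, M=3000.0, S=0.15)
        t[:100] = 20.0  # preterm far outside the window
        model = LMSModel(y, t, config=FitConfig(edf_L=1, edf_M=1, edf_S=1, sex_offset=False))
        assert model.n_excluded == 100
        assert model.y.size == y.size - 100

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(week_range_report=(25, 42))
        with pytest.raises(ValueError):
            FitConfig(edf_M=0.5)
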