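import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salgae.errors import DomainError, UnderdeterminedError
from salgae.salinity_model import (
    SalinityObservation,
    SalinityResponseModel,
    fit,
    fit_log_salinity,
    optimum,
    predict,
)


def grid_search_sse(salinities, pb, n_axis=15):
    """Independent dense 4-D grid oracle for the least-squares objective.

    Evaluates the response curve on a brute-force grid over
    (pmax, a, b, sopt) and returns the lowest sum of squared residuals.
    Deliberately shares no code with the fitter.
    """
    s = np.asarray(salinities, float)
    y = np.asarray(pb, float)
    pmax_ax = np.linspace(y.min(), y.max() + 0.5 * np.ptp(y) + 1e-6, n_axis)
    a_ax = np.linspace(0.0, 3.0 * np.ptp(y) + 1e-6, n_axis)
    b_ax = np.linspace(0.5, 2.0 * np.ptp(s), n_axis)
    sopt_ax = np.linspace(s.min(), s.max(), n_axis)
    best = np.inf
    for pmax in pmax_ax:
        for a in a_ax:
            for b in b_ax:
                # vectorize the innermost two loops
                pred = pmax + a * (
                    np.exp(-(((s[None, :] - sopt_ax[:, None]) / b) ** 2)) - 1.0
                )
                sse = ((pred - y[None, :]) ** 2).sum(axis=1)
                best = min(best, float(sse.min()))
    return best


def observations_from_model(model, salinities, noise_sigma=0.0, rng=None):
    pb = np.array([predict(model, s) for s in salinities], float)
    if noise_sigma > 0:
        pb = pb * np.exp(noise_sigma * rng.standard_normal(pb.shape))
    return [SalinityObservation(float(s), float(p)) for s, p in zip(salinities, pb)]


GRID = np.arange(5.0, 55.0, 5.0)


class TestPredict:
    def test_optimum_returns_pmax(self, true_model):
        assert predict(true_model, 30.0) == 15.0

    def test_reported_maximum_shape(self):
        # any (a, b): at the optimum the exponent vanishes
        m = SalinityResponseModel(pmax=10.14, a=3.0, b=8.0, sopt=21.30)
        assert predict(m, 21.30) == pytest.approx(10.14)

    def test_far_field_asymptote(self, true_model):
        assert predict(true_model, 30.0 + 10 * 15.0) == pytest.approx(5.0, abs=1e-9)

    def test_nonpositive_salinity_rejected(self, true_model):
        with pytest.raises(DomainError):
            predict(true_model, 0.0)
        with pytest.raises(DomainError):
            predict(true_model, -5.0)

    @given(d=st.floats(0, 60))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_about_optimum(self, d):
        m = SalinityResponseModel(pmax=15.0, a=10.0, b=15.0, sopt=70.0)
        lo, hi = 70.0 - d, 70.0 + d
        if lo <= 0:
            return
        assert predict(m, lo) == pytest.approx(predict(m, hi), rel=1e-12)

    @given(d1=st.floats(0, 30), d2=st.floats(0, 30))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_distance_from_optimum(self, d1, d2):
        m = SalinityResponseModel(pmax=15.0, a=10.0, b=15.0, sopt=50.0)
        near, far = sorted([d1, d2])
        assert predict(m, 50.0 + near) >= predict(m, 50.0 + far) - 1e-12


class TestOptimum:
    def test_round_trip(self):
        m = SalinityResponseModel(pmax=15.19, a=9.0, b=12.0, sopt=30.99)
        assert optimum(m) == (30.99, 15.19)

    def test_log10_back_transform(self):
        m = SalinityResponseModel(pmax=5.0, a=1.0, b=0.5, sopt=1.0, transform="log10")
        sopt_psu, _ = optimum(m)
        assert sopt_psu == pytest.approx(10.0)


class TestFit:
    def test_noiseless_recovery(self, true_model):
        obs = observations_from_model(true_model, GRID)
        fitted, diag = fit(obs, seed=0)
        for name in ("pmax", "a", "b", "sopt"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(true_model, name), rel=1e-6
            )
        assert diag.rmse < 1e-8

    def test_underdetermined_rejected(self, true_model):
        obs = observations_from_model(true_model, [10.0, 20.0, 30.0])
        with pytest.raises(UnderdeterminedError):
            fit(obs)

    def test_duplicate_salinities_count_once(self, true_model):
        obs = observations_from_model(true_model, [10.0, 10.0, 20.0, 30.0])
        with pytest.raises(UnderdeterminedError):
            fit(obs)

    def test_degenerate_flat_data_flagged_not_rejected(self):
        obs = [SalinityObservation(s, 7.5) for s in [10.0, 20.0, 30.0, 40.0]]
        model, diag = fit(obs)
        assert model.a == 0.0
        assert any("unidentifiable" in w for w in diag.warnings)
        assert predict(model, 25.0) == pytest.approx(7.5)

    def test_objective_beats_grid_oracle(self, true_model):
        rng = np.random.default_rng(7)
        obs = observations_from_model(true_model, GRID, noise_sigma=0.10, rng=rng)
        fitted, diag = fit(obs, seed=7)
        sse_fit = diag.rmse**2 * len(obs)
        sse_grid = grid_search_sse([o.salinity for o in obs], [o.pb for o in obs])
        assert sse_fit <= sse_grid * (1 + 1e-6)

    def test_stochastic_sopt_recovery_small_study(self, true_model):
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            obs = observations_from_model(true_model, GRID, noise_sigma=0.05, rng=rng)
            fitted, _ = fit(obs, seed=seed)
            errs.append(abs(fitted.sopt - true_model.sopt))
        assert np.median(errs) <= 1.5

    def test_seed_reproducibility(self, true_model):
        rng = np.random.default_rng(3)
        obs = observations_from_model(true_model, GRID, noise_sigma=0.05, rng=rng)
        m1, _ = fit(obs, seed=11)
        m2, _ = fit(obs, seed=11)
        assert m1 == m2


class TestFitLogSalinity:
    def test_noiseless_recovery_on_log_scale(self):
        true = SalinityResponseModel(
            pmax=8.0, a=4.0, b=0.4, sopt=np.log10(20.0), transform="log10"
        )
        obs = observations_from_model(true, GRID)
        fitted, diag = fit_log_salinity(obs, seed=0)
        for name in ("pmax", "a", "b", "sopt"):
            assert getattr(fitted, name) == pytest.approx(getattr(true, name), rel=1e-6)
        assert diag.rmse < 1e-8
        sopt_psu, _ = optimum(fitted)
        assert sopt_psu == pytest.approx(20.0, rel=1e-6)

    def test_log_fit_beats_identity_on_log_shaped_data(self):
        true = SalinityResponseModel(
            pmax=8.0, a=6.0, b=0.25, sopt=np.log10(15.0), transform="log10"
        )
        obs = observations_from_model(true, GRID)
        _, diag_log = fit_log_salinity(obs, seed=0)
        _, diag_id = fit(obs, transform="identity", seed=0)
        assert diag_log.rmse < diag_id.rmse

    def test_nonpositive_salinity_rejected_before_transform(self):
        with pytest.raises(DomainError):
            SalinityObservation(salinity=0.0, pb=1.0)


class TestModelInvariants:
    def test_width_must_be_positive(self):
        with pytest.raises(DomainError):
            SalinityResponseModel(pmax=1, a=1, b=0, sopt=30)

    def test_suppression_nonnegative(self):
        with pytest.raises(DomainError):
            SalinityResponseModel(pmax=1, a=-1, b=5, sopt=30)
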