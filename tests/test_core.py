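"""Decay models, IRF convolution, noise variances and fit objectives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimkit import (
    DataError,
    DecayCurve,
    DecayModelSpec,
    FitRange,
    IRF,
    InvalidParameterError,
    NoiseModel,
    TimeGrid,
    convolve_with_irf,
    eval_model,
    noise_variance,
    objective,
    poisson_deviance,
)


class TestEvalModel:
    def test_mono_exponential_value_at_one_lifetime(self):
        # bin of width 2 centered at t = 1 ns
        grid = TimeGrid(3, 2.0)
        spec = DecayModelSpec.mono_exp(Z=0, A=1, tau=1.0)
        out = eval_model(spec, grid)
        assert out[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_amplitude_is_flat_offset(self, grid64):
        spec = DecayModelSpec("multi_exp", Z=5.0, A=[0.0], tau=[2.0])
        assert np.allclose(eval_model(spec, grid64), 5.0)

    def test_stretched_with_h_one_reduces_to_mono(self, grid64):
        st_spec = DecayModelSpec("stretched_exp", Z=3.0, A=[7.0], tau=[1.5], h=1.0)
        me_spec = DecayModelSpec.mono_exp(Z=3.0, A=7.0, tau=1.5)
        np.testing.assert_allclose(
            eval_model(st_spec, grid := TimeGrid(64, 10 / 64)),
            eval_model(me_spec, grid),
            rtol=1e-14,
        )

    def test_time_restarts_at_fit_range_start(self, grid64):
        spec = DecayModelSpec.mono_exp(Z=0, A=1, tau=2.0)
        shifted = eval_model(spec, grid64, FitRange(10, 30))
        fresh = eval_model(spec, grid64, FitRange(0, 20))
        np.testing.assert_allclose(shifted, fresh, rtol=1e-14)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            DecayModelSpec.mono_exp(Z=0, A=1, tau=-1.0)
        with pytest.raises(InvalidParameterError):
            DecayModelSpec("stretched_exp", Z=0, A=[1], tau=[1], h=0.0)

    @given(
        z=st.floats(0, 100),
        amps=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=3),
        taus=st.lists(st.floats(0.05, 20), min_size=3, max_size=3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_nonnegative_multiexp_is_monotone_nonincreasing(self, z, amps, taus):
        spec = DecayModelSpec("multi_exp", Z=z, A=amps, tau=taus[: len(amps)])
        out = eval_model(spec, TimeGrid(64, 0.1))
        assert np.all(np.diff(out) <= 1e-12 * max(1.0, out[0]))


class TestConvolveWithIRF:
    def test_unit_impulse_is_identity(self, grid64, rng):
        irf = np.zeros(grid64.n_bins)
        irf[0] = 1.0
        model = rng.random(grid64.n_bins)
        np.testing.assert_allclose(
            convolve_with_irf(model, IRF(grid64, irf)), model, rtol=1e-14
        )

    def test_zero_model_gives_zero(self, grid64, rng):
        irf = IRF(grid64, rng.random(grid64.n_bins))
        out = convolve_with_irf(np.zeros(grid64.n_bins), irf)
        assert np.all(out == 0)

    def test_matches_double_loop_oracle(self, rng):
        n = 16
        grid = TimeGrid(n, 0.5)
        model = rng.random(n)
        irf_counts = rng.random(n)
        kernel = irf_counts / irf_counts.sum()
        expected = np.zeros(n)
        for j in range(n):
            for k in range(j + 1):
                expected[j] += kernel[k] * model[j - k]
        out = convolve_with_irf(model, IRF(grid, irf_counts))
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_linearity(self, rng):
        grid = TimeGrid(32, 0.3)
        irf = IRF(grid, rng.random(32))
        m1, m2 = rng.random(32), rng.random(32)
        a, b = 2.5, -1.25
        np.testing.assert_allclose(
            convolve_with_irf(a * m1 + b * m2, irf),
            a * convolve_with_irf(m1, irf) + b * convolve_with_irf(m2, irf),
            rtol=1e-12, atol=1e-12,
        )

    def test_all_zero_irf_rejected(self, grid64):
        with pytest.raises(DataError):
            IRF(grid64, np.zeros(grid64.n_bins))
        with pytest.raises(DataError):
            convolve_with_irf(np.ones(8), np.zeros(8))


class TestNoiseVariance:
    @pytest.mark.parametrize(
        "data,expected",
        [(4.0, 15.0), (0.0, 15.0), (14.9, 15.0), (100.0, 100.0), (15.0, 15.0)],
    )
    def test_poisson_floor_at_fifteen(self, data, expected):
        out = noise_variance(NoiseModel("poisson"), np.array([data]))
        assert out[0] == expected

    def test_gaussian_floors_at_one(self):
        out = noise_variance(NoiseModel("gaussian"), np.array([0.0, 0.5, 7.0]))
        np.testing.assert_array_equal(out, [1.0, 1.0, 7.0])

    def test_constant_everywhere(self):
        out = noise_variance(NoiseModel("constant", sigma2=2.0), np.arange(5.0))
        assert np.all(out == 2.0)

    def test_given_passthrough_and_validation(self):
        var = np.array([1.0, 2.0, 3.0])
        out = noise_variance(NoiseModel("given", variances=var), np.zeros(3))
        np.testing.assert_array_equal(out, var)
        with pytest.raises(InvalidParameterError):
            NoiseModel("given", variances=np.array([1.0, 0.0]))
        with pytest.raises(DataError):
            noise_variance(NoiseModel("given", variances=var), np.zeros(4))

    def test_mle_has_no_variances(self):
        with pytest.raises(InvalidParameterError):
            noise_variance(NoiseModel("mle"), np.ones(3))

    def test_poisson_floor_is_fixed(self):
        with pytest.raises(InvalidParameterError):
            NoiseModel("poisson", poisson_floor=10.0)


class TestObjective:
    @pytest.mark.parametrize("kind", ["constant", "gaussian", "poisson", "mle"])
    def test_perfect_model_scores_zero(self, kind):
        y = np.array([4.0, 16.0, 25.0])
        noise = (
            NoiseModel("constant", sigma2=2.0) if kind == "constant" else NoiseModel(kind)
        )
        assert objective(y, y.copy(), noise) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_hand_value(self):
        # var_i = y_i: (4-6)^2/4 + (16-12)^2/16 = 1 + 1
        val = objective(
            np.array([4.0, 16.0]), np.array([6.0, 12.0]), NoiseModel("gaussian")
        )
        assert val == pytest.approx(2.0, abs=1e-12)

    def test_mle_hand_value(self):
        # 2*(6-4+4*ln(4/6)) = 0.756277...
        val = objective(np.array([4.0]), np.array([6.0]), NoiseModel("mle"))
        assert val == pytest.approx(2 * (6 - 4 + 4 * np.log(4 / 6)), abs=1e-12)
        assert val == pytest.approx(0.75628, abs=5e-6)

    def test_mle_zero_count_term_is_2f(self):
        val = objective(np.array([0.0]), np.array([3.0]), NoiseModel("mle"))
        assert val == pytest.approx(6.0, abs=1e-12)

    def test_mle_rejects_nonpositive_model(self):
        with pytest.raises(InvalidParameterError):
            objective(np.array([1.0]), np.array([0.0]), NoiseModel("mle"))

    def test_invariant_to_bins_outside_fit_range(self, grid64, rng):
        fr = FitRange(5, 40)
        y = rng.poisson(50.0, grid64.n_bins).astype(float)
        model = np.full(len(fr), 48.0)
        for kind in ("gaussian", "poisson"):
            curve1 = DecayCurve(grid64, y)
            y2 = y.copy()
            y2[40:] = 999.0  # outside the range
            curve2 = DecayCurve(grid64, y2)
            noise = NoiseModel(kind)
            assert objective(curve1, model, noise, fr) == objective(
                curve2, model, noise, fr
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_deviance_nonnegative_zero_iff_equal(self, seed):
        r = np.random.default_rng(seed)
        y = r.poisson(20.0, 32).astype(float) + 1.0  # strictly positive
        f = y * np.exp(r.normal(0, 0.2, 32))
        d = poisson_deviance(y, f)
        assert d >= 0
        assert poisson_deviance(y, y.copy()) == pytest.approx(0.0, abs=1e-12)
        if not np.allclose(f, y):
            assert d > 0


class TestContainers:
    def test_fit_range_validation(self, grid64):
        with pytest.raises(DataError):
            FitRange(5, 5)
        with pytest.raises(DataError):
            FitRange(0, 100).validate(grid64)
        with pytest.raises(DataError):
            FitRange(0, 4).validate(grid64, n_free=3)  # needs >= 3 + n_free bins

    def test_grid_invariants(self):
        with pytest.raises(DataError):
            TimeGrid(2, 0.1)
        with pytest.raises(DataError):
            TimeGrid(10, -0.1)
        g = TimeGrid(4, 0.5, origin_ns=1.0)
        np.testing.assert_allclose(g.bin_centers(), [1.25, 1.75, 2.25, 2.75])

    def test_negative_counts_rejected(self, grid64):
        with pytest.raises(DataError):
            DecayCurve(grid64, np.full(grid64.n_bins, -1.0))
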