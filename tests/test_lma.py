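"""Levenberg-Marquardt fitting: oracles, invariants, error estimates."""

import numpy as np
import pytest

from flimkit import (
    DecayCurve,
    DecayModelSpec,
    FitConfig,
    FitError,
    FitRange,
    IRF,
    NoiseModel,
    TimeGrid,
    default_initial_estimate,
    estimate_errors,
    eval_model,
    fit_lma,
    simulate_transient,
)


def _poisson_curve(spec, grid, photons, seed):
    return simulate_transient(spec, grid, photons, seed=seed)


class TestNoiselessFits:
    def test_truth_start_stays_at_truth(self, grid256, mono_spec, noiseless_mono):
        cfg = FitConfig(noise=NoiseModel("gaussian"), initial=mono_spec)
        res = fit_lma(noiseless_mono, cfg)
        assert res.converged
        assert res.reduced_chisq == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            res.spec.to_vector(), mono_spec.to_vector(), rtol=1e-9
        )

    def test_recovers_from_default_start(self, grid256, mono_spec, noiseless_mono):
        res = fit_lma(noiseless_mono, FitConfig(noise=NoiseModel("constant", sigma2=1.0)))
        assert res.spec.tau[0] == pytest.approx(2.0, rel=1e-7)
        assert res.spec.Z == pytest.approx(10.0, rel=1e-5)

    def test_two_component_noiseless(self, grid256):
        spec = DecayModelSpec("multi_exp", Z=0, A=[300, 120], tau=[0.5, 2.5])
        curve = DecayCurve(grid256, eval_model(spec, grid256))
        init = DecayModelSpec("multi_exp", Z=1.0, A=[200, 200], tau=[0.3, 3.5])
        res = fit_lma(
            curve,
            FitConfig(noise=NoiseModel("constant", sigma2=1.0), initial=init),
            n_components=2,
        )
        np.testing.assert_allclose(np.sort(res.spec.tau), [0.5, 2.5], rtol=1e-6)

    def test_stretched_exponential_recovery(self, grid256):
        truth = DecayModelSpec("stretched_exp", Z=2.0, A=[500], tau=[1.5], h=1.6)
        curve = DecayCurve(grid256, eval_model(truth, grid256))
        init = DecayModelSpec("stretched_exp", Z=0.0, A=[400], tau=[2.0], h=1.0)
        res = fit_lma(
            curve,
            FitConfig(noise=NoiseModel("constant", sigma2=1.0), initial=init),
            kind="stretched_exp",
        )
        assert res.spec.tau[0] == pytest.approx(1.5, rel=1e-4)
        assert res.spec.h == pytest.approx(1.6, rel=1e-4)


class TestGridSearchOracle:
    def test_two_free_parameters_match_exhaustive_grid(self, grid64, rng):
        # Z fixed at truth; brute-force chi2 over a 1000x1000 (A, tau) grid
        truth = DecayModelSpec.mono_exp(Z=0.0, A=1.0, tau=2.2)
        curve = _poisson_curve(truth, grid64, 20000, seed=101)
        noise = NoiseModel("poisson")
        res = fit_lma(curve, FitConfig(noise=noise, fixed_values={"Z": 0.0}))

        y = curve.counts
        w = 1.0 / np.maximum(y, 15.0)
        t = grid64.bin_centers()
        a_grid = np.linspace(0.5, 1.5, 1000) * y.max()
        tau_grid = np.linspace(1.5, 3.0, 1000)
        best = (np.inf, None, None)
        for tau in tau_grid:
            b = np.exp(-t / tau)
            # chi2(A) is quadratic in A; evaluate on the full A grid
            chi2 = (
                (w * y * y).sum()
                - 2 * a_grid * (w * y * b).sum()
                + a_grid**2 * (w * b * b).sum()
            )
            j = int(np.argmin(chi2))
            if chi2[j] < best[0]:
                best = (chi2[j], a_grid[j], tau)
        _, a_best, tau_best = best
        assert abs(res.spec.A[0] - a_best) <= a_grid[1] - a_grid[0]
        assert abs(res.spec.tau[0] - tau_best) <= tau_grid[1] - tau_grid[0]


class TestEstimateErrors:
    def test_identity_alpha(self):
        np.testing.assert_allclose(estimate_errors(np.eye(3), 1.0), np.ones(3))

    def test_diagonal_alpha(self):
        np.testing.assert_allclose(
            estimate_errors(np.diag([4.0, 25.0]), 1.0), [0.5, 0.2]
        )

    def test_singular_alpha_raises(self):
        with pytest.raises(FitError):
            estimate_errors(np.zeros((2, 2)))

    def test_coverage_of_one_sigma_interval(self, grid64):
        # ~68% of Poisson replicates should bracket the true tau within 1 SE
        truth = DecayModelSpec.mono_exp(Z=0, A=1, tau=2.0)
        cfg = FitConfig(noise=NoiseModel("mle"), fixed_values={"Z": 0.0})
        hits = 0
        n_rep = 1000
        for s in range(n_rep):
            curve = _poisson_curve(truth, grid64, 3000, seed=900_000 + s)
            res = fit_lma(curve, cfg)
            err = dict(zip(res.free_names, res.std_errors))["tau1"]
            hits += abs(res.spec.tau[0] - 2.0) <= err
        assert hits / n_rep == pytest.approx(0.68, abs=0.04)


class TestInvariantsAndOptions:
    def test_constant_noise_estimates_invariant_to_sigma2(self, grid256, mono_spec):
        curve = _poisson_curve(mono_spec, grid256, 50000, seed=7)
        r1 = fit_lma(curve, FitConfig(noise=NoiseModel("constant", sigma2=1.0)))
        r2 = fit_lma(curve, FitConfig(noise=NoiseModel("constant", sigma2=25.0)))
        np.testing.assert_allclose(r1.spec.to_vector(), r2.spec.to_vector(), rtol=1e-6)
        assert r1.objective_value == pytest.approx(25.0 * r2.objective_value, rel=1e-6)

    def test_fixing_true_z_never_hurts_tau_rmse(self, grid64):
        truth = DecayModelSpec.mono_exp(Z=5.0, A=200.0, tau=1.8)
        expected = eval_model(truth, grid64)
        free_err, fixed_err = [], []
        for s in range(60):
            rng = np.random.default_rng(3000 + s)
            curve = DecayCurve(grid64, rng.poisson(expected).astype(float))
            rf = fit_lma(curve, FitConfig(noise=NoiseModel("mle")))
            rz = fit_lma(
                curve, FitConfig(noise=NoiseModel("mle"), fixed_values={"Z": 5.0})
            )
            free_err.append((rf.spec.tau[0] - 1.8) ** 2)
            fixed_err.append((rz.spec.tau[0] - 1.8) ** 2)
        assert np.mean(fixed_err) <= np.mean(free_err)

    def test_mle_and_gaussian_agree_at_high_counts(self, grid256, mono_spec):
        curve = _poisson_curve(mono_spec, grid256, 100_000, seed=17)
        rg = fit_lma(curve, FitConfig(noise=NoiseModel("gaussian")))
        rm = fit_lma(curve, FitConfig(noise=NoiseModel("mle")))
        assert rm.spec.tau[0] == pytest.approx(rg.spec.tau[0], rel=0.02)

    def test_restraints_clamp_parameters(self, grid256, mono_spec):
        curve = _poisson_curve(mono_spec, grid256, 10000, seed=23)
        res = fit_lma(
            curve,
            FitConfig(
                noise=NoiseModel("poisson"),
                restraints={"tau1": (2.5, 3.5)},  # excludes the true 2.0
            ),
        )
        assert 2.5 <= res.spec.tau[0] <= 3.5

    def test_all_fixed_rejected(self, grid256, mono_spec, noiseless_mono):
        with pytest.raises(Exception):
            fit_lma(
                noiseless_mono,
                FitConfig(fixed_values={"Z": 0, "A1": 1, "tau1": 1}),
            )

    def test_objective_nonincreasing_reflected_in_convergence(self, grid256, mono_spec):
        curve = _poisson_curve(mono_spec, grid256, 8000, seed=31)
        init = DecayModelSpec.mono_exp(Z=0.0, A=curve.counts.max(), tau=5.0)
        cfg = FitConfig(noise=NoiseModel("poisson"), initial=init)
        res = fit_lma(curve, cfg)
        start_obj = float(
            np.sum(
                (curve.counts - eval_model(init, grid256)) ** 2
                / np.maximum(curve.counts, 15.0)
            )
        )
        assert res.objective_value <= start_obj
        assert res.converged


class TestIRFReconvolution:
    def test_delta_irf_equals_no_irf(self, grid256, mono_spec):
        curve = _poisson_curve(mono_spec, grid256, 20000, seed=41)
        delta = np.zeros(grid256.n_bins)
        delta[0] = 1.0
        cfg = FitConfig(noise=NoiseModel("poisson"))
        r0 = fit_lma(curve, cfg)
        r1 = fit_lma(curve, cfg, irf=IRF(grid256, delta))
        np.testing.assert_allclose(r0.spec.to_vector(), r1.spec.to_vector(), rtol=1e-9)

    def test_reconvolution_recovers_true_lifetime(self, grid256):
        # data distorted by a broad IRF: plain fit is biased, reconvolution is not
        from flimkit import convolve_with_irf

        t = grid256.bin_centers()
        irf_counts = np.exp(-0.5 * ((t - 1.0) / 0.15) ** 2)
        irf = IRF(grid256, irf_counts)
        truth = DecayModelSpec.mono_exp(Z=0, A=1000, tau=2.0)
        distorted = convolve_with_irf(eval_model(truth, grid256), irf)
        curve = DecayCurve(grid256, distorted)
        init = DecayModelSpec.mono_exp(Z=0.0, A=800.0, tau=3.0)
        cfg = FitConfig(noise=NoiseModel("constant", sigma2=1.0), initial=init)
        res = fit_lma(curve, cfg, irf=irf)
        assert res.spec.tau[0] == pytest.approx(2.0, rel=1e-6)
        res_plain = fit_lma(curve, cfg)
        assert abs(res_plain.spec.tau[0] - 2.0) > 0.05  # bias without the IRF


class TestDefaultInitialEstimate:
    def test_mono_matches_rld(self, noiseless_mono):
        from flimkit import fit_rld

        init = default_initial_estimate(noiseless_mono)
        rld = fit_rld(noiseless_mono).spec
        np.testing.assert_allclose(init.to_vector(), rld.to_vector(), rtol=1e-12)

    def test_two_component_geometric_split(self, grid256):
        spec = DecayModelSpec.mono_exp(Z=0, A=100, tau=1.0)
        curve = DecayCurve(grid256, eval_model(spec, grid256))
        init = default_initial_estimate(curve, n_components=2)
        np.testing.assert_allclose(init.tau, [0.5, 2.0], rtol=1e-9)
        np.testing.assert_allclose(init.A, [50, 50], rtol=1e-9)

    def test_flat_curve_fallback_is_positive(self, grid64):
        flat = DecayCurve(grid64, np.full(grid64.n_bins, 9.0))
        init = default_initial_estimate(flat)
        assert init.tau[0] > 0
        assert init.A[0] > 0
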