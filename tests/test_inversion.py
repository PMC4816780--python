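import math

import numpy as np
import pytest

from cmcdcm import (
    ERFDataset,
    ExtrinsicTarget,
    FitOptions,
    InputSpec,
    LeadField,
    ModulationSpec,
    NetworkModel,
    Parameterization,
    ParamPrior,
    PriorSpec,
    SimulationGrid,
    Source,
    fit,
    free_energy,
    jacobian,
    predict,
    simulate_conditions,
)
from conftest import make_two_source_model

GRID = SimulationGrid(1.0, 201.0, 4.0)
INPUT = InputSpec()


def make_dataset(model, leadfield, noise_sd=0.0, seed=0, grid=GRID):
    ds = simulate_conditions(model, INPUT, grid, leadfield)
    if noise_sd:
        rng = np.random.default_rng(seed)
        ds.data = ds.data + rng.normal(0, noise_sd, ds.data.shape)
    ds.leadfield = leadfield
    return ds


class TestParameterization:
    def test_free_and_fixed_split(self, two_source_model):
        priors = PriorSpec.for_model(two_source_model)
        par = Parameterization(two_source_model, INPUT, priors)
        assert set(par.names) >= {"att_back", "att_gain", "exp_fwd"}
        clamped = Parameterization(two_source_model, INPUT, priors.fixed("att_gain"))
        assert "att_gain" not in clamped.names
        assert clamped.n_free == par.n_free - 1

    def test_unknown_parameter_rejected(self, two_source_model):
        priors = PriorSpec.for_model(two_source_model)
        priors.params.append(ParamPrior("not_a_knob", 0.0, 1.0))
        with pytest.raises(KeyError):
            Parameterization(two_source_model, INPUT, priors)

    def test_realize_applies_log_scales(self, two_source_model):
        priors = PriorSpec.for_model(two_source_model)
        par = Parameterization(two_source_model, INPUT, priors)
        theta = par.prior_mean()
        theta[par.names.index("log_af_scale")] = math.log(2)
        model, inp = par.realize(theta)
        assert np.allclose(model.af, 2 * two_source_model.af)
        assert inp.latency == INPUT.latency


class TestPredict:
    def test_deterministic(self, two_source_model, leadfield8):
        par = Parameterization(two_source_model, INPUT, PriorSpec.for_model(two_source_model))
        th = par.prior_mean()
        a = predict(par, th, GRID, leadfield8)
        b = predict(par, th, GRID, leadfield8)
        assert np.array_equal(a, b)

    def test_zero_amplitude_zero_prediction(self, two_source_model, leadfield8):
        par = Parameterization(
            two_source_model, InputSpec(amplitude=0.0), PriorSpec.for_model(two_source_model)
        )
        pred = predict(par, par.prior_mean(), GRID, leadfield8)
        assert np.all(pred == 0)

    def test_every_parameter_moves_the_prediction(self, two_source_model, leadfield8):
        par = Parameterization(two_source_model, INPUT, PriorSpec.for_model(two_source_model))
        jac = jacobian(par, par.prior_mean(), GRID, leadfield8)
        norms = np.linalg.norm(jac, axis=0)
        assert np.all(norms > 0)


class TestJacobian:
    def test_amplitude_column_matches_prediction_in_linear_regime(
        self, two_source_model, leadfield8
    ):
        # with a weak input the response is linear in the drive, so the
        # sensitivity to the log-amplitude equals the prediction itself
        par = Parameterization(
            two_source_model, InputSpec(amplitude=1e-3), PriorSpec.for_model(two_source_model)
        )
        th = par.prior_mean()
        jac = jacobian(par, th, GRID, leadfield8)
        col = jac[:, par.names.index("log_input_amplitude")]
        pred = predict(par, th, GRID, leadfield8).ravel()
        assert np.allclose(col, pred, rtol=0.02, atol=1e-9 * np.abs(pred).max())

    def test_mirrored_hemispheres_have_mirrored_columns(self):
        sources = [
            Source("lA1", (-42, -22, 7), 1),
            Source("rA1", (46, -14, 8), 1),
            Source("lSTG", (-60, -48, 20), 2),
            Source("rSTG", (56, -40, 18), 2),
        ]
        af = np.zeros((4, 4))
        ab = np.zeros((4, 4))
        af[2, 0] = af[3, 1] = 2.0
        ab[0, 2] = ab[1, 3] = 0.5
        mods = [
            ModulationSpec(
                "attention",
                extrinsic=[
                    ExtrinsicTarget("lSTG", "lA1", "backward", tie="att_back_l"),
                    ExtrinsicTarget("rSTG", "rA1", "backward", tie="att_back_r"),
                ],
            )
        ]
        model = NetworkModel(sources, af, ab, np.array([1.0, 1, 0, 0]), modulations=mods)
        lf = LeadField(np.eye(4))  # sensor k sees source k only
        priors = PriorSpec.for_model(model)
        par = Parameterization(model, INPUT, priors)
        jac = jacobian(par, par.prior_mean(), GRID, lf)
        nt = GRID.n_times
        swap = [1, 0, 3, 2]  # hemisphere exchange on the sensor axis
        jl = jac[:, par.names.index("att_back_l")].reshape(4, 4, nt)
        jr = jac[:, par.names.index("att_back_r")].reshape(4, 4, nt)
        assert np.allclose(jl[:, swap, :], jr, atol=1e-12)

    def test_nonfinite_prediction_raises(self, two_source_model, leadfield8):
        par = Parameterization(
            two_source_model, InputSpec(amplitude=1e308), PriorSpec.for_model(two_source_model)
        )
        with pytest.raises(Exception):
            jacobian(par, par.prior_mean(), GRID, leadfield8)


class TestFreeEnergy:
    def test_posterior_equal_prior_has_zero_complexity(self):
        mu0 = np.array([0.0, 1.0])
        sig0 = np.diag([0.25, 4.0])
        fe = free_energy(np.array([0.3, -0.2]), mu0, sig0, mu0, sig0, 2.0, 9.0, 2.0, 9.0)
        assert fe.complexity == 0.0
        assert fe.f == fe.accuracy

    def test_scalar_gaussian_log_density(self):
        # one residual e at unit noise precision: -e^2/2 - ln(2 pi)/2
        e = 0.7
        empty = np.empty(0)
        fe = free_energy(np.array([e]), empty, np.empty((0, 0)), empty, np.empty((0, 0)),
                         0.0, 1.0, 0.0, 1.0)
        assert fe.f == pytest.approx(-0.5 * e**2 - 0.5 * math.log(2 * math.pi), abs=1e-12)
        assert fe.complexity == 0.0

    def test_larger_residuals_lower_f(self):
        empty = np.empty(0)

        def f_of(e):
            return free_energy(np.array([e]), empty, np.empty((0, 0)), empty,
                               np.empty((0, 0)), 0.0, 1.0, 0.0, 1.0).f

        assert f_of(2.0) < f_of(1.0) < f_of(0.1)

    def test_bookkeeping_is_exact(self):
        mu = np.array([0.2])
        fe = free_energy(np.array([0.5, -0.5]), mu, np.array([[0.1]]), np.array([0.0]),
                         np.array([[0.25]]), 1.0, 2.0, 0.5, 4.0)
        assert fe.f == fe.accuracy - fe.complexity
        assert fe.complexity == fe.kl_params + fe.kl_hyper

    def test_singular_prior_raises_with_diagnostics(self):
        mu = np.array([0.0, 0.0])
        sing = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            free_energy(np.array([0.1]), mu, np.eye(2), mu, sing, 0.0, 1.0, 0.0, 1.0)


class TestFit:
    def test_noiseless_self_consistency(self, leadfield8):
        model = make_two_source_model()  # truth at the prior mean
        ds = make_dataset(model, leadfield8)
        post = fit(model, ds)
        par = Parameterization(model, INPUT, PriorSpec.for_model(model))
        pred = predict(par, post.mean, GRID, leadfield8)
        r = np.corrcoef(pred.ravel(), ds.data.ravel())[0, 1]
        assert r > 0.999
        assert post.converged
        assert np.all(np.diff(post.f_trace) >= 0)

    def test_posterior_covariance_symmetric_psd(self, leadfield8):
        model = make_two_source_model()
        ds = make_dataset(model, leadfield8, noise_sd=0.002, seed=1)
        post = fit(model, ds)
        assert np.allclose(post.cov, post.cov.T)
        assert np.linalg.eigvalsh(post.cov).min() > 0

    def test_fit_is_deterministic(self, leadfield8):
        model = make_two_source_model()
        ds = make_dataset(model, leadfield8, noise_sd=0.002, seed=2)
        opts = FitOptions(max_iter=4)
        a = fit(model, ds, options=opts)
        b = fit(model, ds, options=opts)
        assert np.array_equal(a.mean, b.mean)
        assert a.free_energy == b.free_energy

    def test_recovers_modulation_sign(self, leadfield8):
        truth = make_two_source_model(exp_fwd=0.7)
        ds = make_dataset(truth, leadfield8, noise_sd=0.0)
        post = fit(make_two_source_model(), ds)
        mean, var = post["exp_fwd"]
        assert mean > 0.3
        assert mean - 2 * math.sqrt(var) > 0

    def test_window_contract_ignores_outside_samples(self, leadfield8):
        model = make_two_source_model()
        ds = make_dataset(model, leadfield8, noise_sd=0.002, seed=3)
        corrupted = ERFDataset(
            data=ds.data.copy(), conditions=ds.conditions, times=ds.times,
            sfreq=ds.sfreq, leadfield=leadfield8,
        )
        corrupted.data[:, :, ds.times > 120] += 50.0  # garbage beyond the window
        opts = FitOptions(window=(1.0, 120.0), max_iter=4)
        a = fit(model, ds, options=opts)
        b = fit(model, corrupted, options=opts)
        assert np.array_equal(a.mean, b.mean)
        assert a.free_energy == b.free_energy

    def test_occam_penalty_for_redundant_parameters(self, leadfield8):
        # data carry no modulation effects: freeing extra modulation
        # parameters cannot raise the evidence beyond a small tolerance
        model = make_two_source_model()
        wins = 0
        for seed in range(3):
            ds = make_dataset(model, leadfield8, noise_sd=0.002, seed=10 + seed)
            priors = PriorSpec.for_model(model)
            reduced = fit(model, ds, priors=priors.fixed("att_back", "att_gain"))
            augmented = fit(model, ds, priors=priors)
            if augmented.free_energy <= reduced.free_energy + 0.5:
                wins += 1
        assert wins >= 2

    def test_missing_condition_rejected(self, leadfield8):
        model = make_two_source_model()
        ds = make_dataset(model, leadfield8)
        partial = ERFDataset(
            data=ds.data[:2], conditions=ds.conditions[:2], times=ds.times,
            sfreq=ds.sfreq, leadfield=leadfield8,
        )
        with pytest.raises(ValueError, match="condition"):
            fit(model, partial)

    def test_missing_leadfield_rejected(self, leadfield8):
        model = make_two_source_model()
        ds = make_dataset(model, leadfield8)
        ds.leadfield = None
        with pytest.raises(ValueError, match="lead field"):
            fit(model, ds)
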