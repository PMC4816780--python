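"""Variational-Laplace model inversion.

Fits a :class:`~cmcdcm.network.NetworkModel` to a multi-condition ERF
dataset under a Gaussian observation model with a single isotropic noise
precision ``exp(lambda)``.  Free parameters live on log-scaling coordinates
(extrinsic strengths, condition-modulation b/g, input amplitude) or natural
units (input latency, ms) with Gaussian priors; the posterior is the
Laplace (Gaussian) approximation obtained from an EM-style loop of
Gauss-Newton updates on the mean with step-size halving, closed-form
covariance, and Newton updates of the noise hyperparameter.  The variational
free energy F = accuracy - complexity is the fit objective and the
approximation to the log model evidence used for model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .microcircuit import ExtrinsicTarget, IntrinsicTarget, ModulationSpec
from .network import (
    ERFDataset,
    InputSpec,
    LeadField,
    NetworkModel,
    SimulationGrid,
    simulate_conditions,
)

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "Parameterization",
    "FitOptions",
    "Posterior",
    "FreeEnergy",
    "predict",
    "jacobian",
    "free_energy",
    "fit",
]

LN2PI = math.log(2 * math.pi)


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior for one named parameter; variance 0 fixes it."""

    name: str
    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("prior variance must be >= 0")


@dataclass
class PriorSpec:
    """Priors over model parameters plus the noise log-precision hyperprior.

    Parameter names refer to modulation tie groups and to the built-in
    global coordinates ``log_af_scale``, ``log_ab_scale``,
    ``input_latency`` and ``log_input_amplitude``.  Parameters with zero
    variance are fixed at their prior mean and excluded from the search
    space.
    """

    params: list[ParamPrior]
    lam_mean: float = 4.0
    lam_var: float = 16.0

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in prior")
        if self.lam_var <= 0:
            raise ValueError("hyperprior variance must be > 0")

    @classmethod
    def for_model(
        cls,
        model: NetworkModel,
        extrinsic_scale_var: float = 1 / 16,
        modulation_var: float = 1 / 4,
        latency_mean: float = 20.0,
        latency_var: float = 16.0,
        amplitude_var: float = 1 / 16,
        lam_mean: float = 4.0,
        lam_var: float = 16.0,
    ) -> "PriorSpec":
        """Default priors: one parameter per modulation tie group, global
        log-scales on forward/backward strengths, and the Gaussian input's
        latency (prior mean 20 ms) and log-amplitude."""
        params = [
            ParamPrior("log_af_scale", 0.0, extrinsic_scale_var),
            ParamPrior("log_ab_scale", 0.0, extrinsic_scale_var),
            ParamPrior("input_latency", latency_mean, latency_var),
            ParamPrior("log_input_amplitude", 0.0, amplitude_var),
        ]
        for name in _modulation_groups(model):
            params.append(ParamPrior(name, 0.0, modulation_var))
        return cls(params=params, lam_mean=lam_mean, lam_var=lam_var)

    def fixed(self, *names: str) -> "PriorSpec":
        """Copy with the named parameters clamped (variance 0)."""
        out = [replace(p, var=0.0) if p.name in names else p for p in self.params]
        return replace(self, params=out)

    def get(self, name: str) -> ParamPrior:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)


def _auto_tie(factor: str, target) -> str:
    if isinstance(target, ExtrinsicTarget):
        return f"{factor}:{target.src}->{target.dst}:{target.direction}"
    return f"{factor}:{target.source}:{target.population}"


def _modulation_groups(model: NetworkModel) -> list[str]:
    seen: list[str] = []
    for spec in model.modulations:
        for t in list(spec.extrinsic) + list(spec.intrinsic):
            name = t.tie or _auto_tie(spec.factor, t)
            if name not in seen:
                seen.append(name)
    return seen


class Parameterization:
    """Maps a free-parameter vector onto a model and input specification.

    Binds a :class:`NetworkModel`, a base :class:`InputSpec` and a
    :class:`PriorSpec`; zero-variance parameters are held at their prior
    mean and carry no Jacobian column.
    """

    def __init__(self, model: NetworkModel, input_spec: InputSpec, priors: PriorSpec):
        self.model = model
        self.input_spec = input_spec
        self.priors = priors
        groups = set(_modulation_groups(model))
        builtin = {"log_af_scale", "log_ab_scale", "input_latency", "log_input_amplitude"}
        for p in priors.params:
            if p.name not in groups and p.name not in builtin:
                raise KeyError(f"prior parameter {p.name!r} matches no model coordinate")
        self.free = [p for p in priors.params if p.var > 0]
        self.fixed = {p.name: p.mean for p in priors.params if p.var == 0}

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.free]

    @property
    def n_free(self) -> int:
        return len(self.free)

    def prior_mean(self) -> np.ndarray:
        return np.array([p.mean for p in self.free])

    def prior_cov(self) -> np.ndarray:
        return np.diag([p.var for p in self.free])

    def realize(self, theta: np.ndarray) -> tuple[NetworkModel, InputSpec]:
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_free,):
            raise ValueError("parameter vector length mismatch")
        values = dict(self.fixed)
        values.update(zip(self.names, theta))

        model = self.model
        mods = []
        for spec in model.modulations:
            ext = [
                replace(t, b=values.get(t.tie or _auto_tie(spec.factor, t), t.b))
                for t in spec.extrinsic
            ]
            intr = [
                replace(t, g=values.get(t.tie or _auto_tie(spec.factor, t), t.g))
                for t in spec.intrinsic
            ]
            mods.append(
                ModulationSpec(
                    spec.factor, ext, intr, activity_dependent=spec.activity_dependent
                )
            )
        model = model.with_modulations(mods)
        model = model.scaled(
            log_af=values.get("log_af_scale", 0.0), log_ab=values.get("log_ab_scale", 0.0)
        )
        inp = InputSpec(
            latency=values.get("input_latency", self.input_spec.latency),
            dispersion=self.input_spec.dispersion,
            amplitude=self.input_spec.amplitude
            * math.exp(values.get("log_input_amplitude", 0.0)),
        )
        return model, inp


def predict(
    parameterization: Parameterization,
    theta: np.ndarray,
    grid: SimulationGrid,
    leadfield: LeadField,
    solver_dt: float = 0.5,
) -> np.ndarray:
    """Multi-condition sensor prediction at parameter point ``theta``.

    Deterministic: identical inputs give identical output arrays of shape
    (n_conditions, n_sensors, n_times).
    """
    model, inp = parameterization.realize(theta)
    return simulate_conditions(model, inp, grid, leadfield, solver_dt=solver_dt).data


def jacobian(
    parameterization: Parameterization,
    theta: np.ndarray,
    grid: SimulationGrid,
    leadfield: LeadField,
    h: float = 1e-3,
    solver_dt: float = 0.5,
) -> np.ndarray:
    """Central finite-difference sensitivity of the vectorized prediction.

    The step for parameter k is ``h * max(1, prior SD)`` so parameters in
    natural units (latency, ms) are perturbed on a commensurate scale.
    Columns follow ``parameterization.names``; zero-variance parameters have
    no column.
    """
    theta = np.asarray(theta, float)
    cols = []
    sds = np.sqrt([p.var for p in parameterization.free])
    for k in range(parameterization.n_free):
        step = h * max(1.0, sds[k])
        up = np.array(theta)
        up[k] += step
        down = np.array(theta)
        down[k] -= step
        yu = predict(parameterization, up, grid, leadfield, solver_dt)
        yd = predict(parameterization, down, grid, leadfield, solver_dt)
        if not (np.all(np.isfinite(yu)) and np.all(np.isfinite(yd))):
            raise FloatingPointError(
                f"non-finite prediction while differentiating {parameterization.names[k]!r}"
            )
        cols.append((yu - yd).ravel() / (2 * step))
    return np.column_stack(cols) if cols else np.empty((0, 0))


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreeEnergy:
    """Variational free energy and its exact bookkeeping.

    ``f == accuracy - complexity`` and
    ``complexity == kl_params + kl_hyper`` hold to machine precision.
    """

    f: float
    accuracy: float
    complexity: float
    kl_params: float
    kl_hyper: float


def _logdet_psd(mat: np.ndarray, label: str) -> float:
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0 or not np.isfinite(logdet):
        cond = np.linalg.cond(mat)
        raise np.linalg.LinAlgError(
            f"{label} is singular or indefinite (condition number {cond:.3e})"
        )
    return float(logdet)


def free_energy(
    residuals: np.ndarray,
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    lam: float,
    lam_var: float,
    lam_prior_mean: float,
    lam_prior_var: float,
    jac: np.ndarray | None = None,
) -> FreeEnergy:
    """Free energy F = accuracy - complexity for a Gaussian posterior.

    Accuracy is the expected Gaussian log-likelihood of the residuals under
    the noise precision ``exp(lam)`` (including the ``tr(J Sigma J^T)``
    correction when the Jacobian is supplied); complexity is the KL
    divergence of the parameter posterior from its prior plus the KL term of
    the Gaussian noise-hyperparameter belief N(lam, lam_var).
    """
    r = np.asarray(residuals, float).ravel()
    n = r.size
    mu = np.asarray(post_mean, float)
    mu0 = np.asarray(prior_mean, float)
    sig = np.asarray(post_cov, float)
    sig0 = np.asarray(prior_cov, float)
    p = mu.size
    if mu0.shape != mu.shape or sig.shape != (p, p) or sig0.shape != (p, p):
        raise ValueError("inconsistent parameter dimensions in free_energy")

    quad = float(r @ r)
    if jac is not None and p:
        quad += float(np.sum((jac @ sig) * jac))
    accuracy = -0.5 * math.exp(lam) * quad + 0.5 * n * lam - 0.5 * n * LN2PI

    if p:
        ld0 = _logdet_psd(sig0, "prior covariance")
        ld = _logdet_psd(sig, "posterior covariance")
        prec0 = np.linalg.inv(sig0)
        d = mu - mu0
        kl_params = 0.5 * (
            float(np.trace(prec0 @ sig)) + float(d @ prec0 @ d) - p + ld0 - ld
        )
    else:
        kl_params = 0.0
    kl_hyper = 0.5 * (
        lam_var / lam_prior_var
        + (lam - lam_prior_mean) ** 2 / lam_prior_var
        - 1.0
        + math.log(lam_prior_var / lam_var)
    )
    complexity = kl_params + kl_hyper
    return FreeEnergy(
        f=accuracy - complexity,
        accuracy=accuracy,
        complexity=complexity,
        kl_params=kl_params,
        kl_hyper=kl_hyper,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Inversion options (convergence, steps, window, solver)."""

    tol: float = 1e-2  # nats
    consecutive: int = 4
    max_iter: int = 64
    fd_step: float = 1e-3
    solver_dt: float = 0.5
    max_halvings: int = 5
    hyper_iters: int = 4
    inner_steps: int = 8  # Gauss-Newton steps per Jacobian refresh
    window: tuple[float, float] | None = None  # ms; None = full dataset window
    center: bool = True


@dataclass
class Posterior:
    """Gaussian parameter posterior with free-energy diagnostics."""

    mean: np.ndarray
    cov: np.ndarray
    param_names: list[str]
    lam: float
    lam_var: float
    free_energy: float
    accuracy: float
    complexity: float
    f_trace: np.ndarray
    converged: bool
    model_id: str = ""
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        self.f_trace = np.asarray(self.f_trace, float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("posterior covariance shape mismatch")

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def __getitem__(self, name: str) -> tuple[float, float]:
        k = self.param_names.index(name)
        return float(self.mean[k]), float(self.cov[k, k])


def _center(arr: np.ndarray) -> np.ndarray:
    return arr - arr.mean(axis=(0, 2), keepdims=True)


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(times.size, bool)
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"analysis window {window} selects no samples")
    return mask


def fit(
    model: NetworkModel,
    dataset: ERFDataset,
    priors: PriorSpec | None = None,
    options: FitOptions | None = None,
    leadfield: LeadField | None = None,
    input_spec: InputSpec | None = None,
) -> Posterior:
    """Invert ``model`` against ``dataset`` by variational Laplace.

    Conditions present in the model's design must all be present in the
    dataset.  Returns the best-free-energy Gaussian posterior; the trace of
    accepted free-energy values is non-decreasing by construction (proposed
    Gauss-Newton steps that lower F are halved and ultimately rejected).
    """
    opts = options or FitOptions()
    priors = priors or PriorSpec.for_model(model)
    lf = leadfield or dataset.leadfield
    if lf is None:
        raise ValueError("a lead field is required (dataset.leadfield or argument)")
    from .network import CONDITIONS

    missing = [c for c in CONDITIONS if c not in dataset.conditions]
    if missing:
        raise ValueError(f"dataset lacks conditions {missing}")

    mask = _window_mask(dataset.times, opts.window)
    times = dataset.times[mask]
    grid = SimulationGrid(
        t_start=float(times[0]), t_end=float(times[-1]), dt=float(times[1] - times[0])
    )
    order = [dataset.conditions.index(c) for c in CONDITIONS]
    y = dataset.data[order][:, :, mask]
    if opts.center:
        y = _center(y)
    yv = y.ravel()
    n = yv.size

    par = Parameterization(model, input_spec or InputSpec(), priors)
    theta = par.prior_mean()
    mu0 = par.prior_mean()
    sig0 = par.prior_cov()
    prec0 = np.linalg.inv(sig0) if par.n_free else np.empty((0, 0))
    lam, lam_var = priors.lam_mean, priors.lam_var
    lam0, v0 = priors.lam_mean, priors.lam_var

    def prediction(th: np.ndarray) -> np.ndarray:
        pred = predict(par, th, grid, lf, opts.solver_dt)
        return (_center(pred) if opts.center else pred).ravel()

    def hyper_update(rss_plus_trace: float, lam: float) -> tuple[float, float]:
        # Maximize F over the noise log-precision.  F is concave in lam, so
        # Newton from the maximum-likelihood point with clipped steps
        # converges; the prior on lam only nudges the ML solution.
        q = max(rss_plus_trace, 1e-300)
        lam = min(max(math.log(n / q), lam0 - 40.0), lam0 + 40.0)
        hess = -1.0 / v0
        for _ in range(opts.hyper_iters):
            e = math.exp(lam)
            grad = 0.5 * n - 0.5 * e * q - (lam - lam0) / v0
            hess = -0.5 * e * q - 1.0 / v0
            lam = lam - max(-4.0, min(4.0, grad / hess))
        return lam, -1.0 / hess

    def posterior_at(th, r, jac, lam, lam_var):
        jtj = jac.T @ jac
        sig = np.linalg.inv(math.exp(lam) * jtj + prec0) if par.n_free else np.empty((0, 0))
        sig = 0.5 * (sig + sig.T)
        trace = float(np.sum(jtj * sig)) if par.n_free else 0.0
        fe = free_energy(r, th, sig, mu0, sig0, lam, lam_var, lam0, v0, jac=jac)
        return sig, trace, fe

    r = yv - prediction(theta)
    jac = jacobian(par, theta, grid, lf, opts.fd_step, opts.solver_dt)
    # initialize hyperparameter from the prior-mean residuals
    lam, lam_var = hyper_update(float(r @ r), lam)
    sig, trace, fe = posterior_at(theta, r, jac, lam, lam_var)
    lam, lam_var = hyper_update(float(r @ r) + trace, lam)
    sig, trace, fe = posterior_at(theta, r, jac, lam, lam_var)

    best = dict(theta=theta, r=r, jac=jac, sig=sig, lam=lam, lam_var=lam_var, fe=fe)
    f_trace = [fe.f]
    converged = False
    small = 0
    it = 0
    for it in range(1, opts.max_iter + 1 if par.n_free else 1):
        jac = jacobian(par, best["theta"], grid, lf, opts.fd_step, opts.solver_dt)
        f_before = best["fe"].f
        # several Gauss-Newton steps reuse one Jacobian; each proposal is
        # halved until it improves F or is rejected
        for _ in range(max(1, opts.inner_steps)):
            e = math.exp(best["lam"])
            jtj = jac.T @ jac
            sig = np.linalg.inv(e * jtj + prec0)
            step = sig @ (e * jac.T @ best["r"] - prec0 @ (best["theta"] - mu0))
            improved = False
            alpha = 1.0
            for _ in range(opts.max_halvings + 1):
                cand = best["theta"] + alpha * step
                try:
                    r_c = yv - prediction(cand)
                except Exception:
                    alpha *= 0.5
                    continue
                lam_c, lamv_c = hyper_update(float(r_c @ r_c), best["lam"])
                sig_c, trace_c, fe_c = posterior_at(cand, r_c, jac, lam_c, lamv_c)
                lam_c, lamv_c = hyper_update(float(r_c @ r_c) + trace_c, lam_c)
                sig_c, trace_c, fe_c = posterior_at(cand, r_c, jac, lam_c, lamv_c)
                if fe_c.f > best["fe"].f:
                    best = dict(
                        theta=cand, r=r_c, jac=jac, sig=sig_c,
                        lam=lam_c, lam_var=lamv_c, fe=fe_c,
                    )
                    f_trace.append(fe_c.f)
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
        small = small + 1 if best["fe"].f - f_before < opts.tol else 0
        if small >= opts.consecutive:
            converged = True
            break
    if par.n_free == 0:
        converged = True  # nothing to optimize beyond the hyperparameter

    fe = best["fe"]
    return Posterior(
        mean=best["theta"],
        cov=best["sig"],
        param_names=par.names,
        lam=best["lam"],
        lam_var=best["lam_var"],
        free_energy=fe.f,
        accuracy=fe.accuracy,
        complexity=fe.complexity,
        f_trace=np.array(f_trace),
        converged=converged,
        model_id=model.name,
        n_iter=it,
    )
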