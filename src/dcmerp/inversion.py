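"""Variational-Laplace inversion of one evoked-response pair.

Latent parameters are log-scalings: each physical quantity equals its
prior mean times exp(theta), so theta = 0 is the prior.  A Gaussian prior
over theta and a Gaussian prior over the log observation-noise precision
lambda define a free-energy objective (accuracy minus complexity) that is
ascended by Gauss-Newton steps with Levenberg regularization; steps that
would lower the free energy are rejected and the damping increased, so
the accepted trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neural_mass import (
    CompiledVariant,
    EvokedResponse,
    ModelVariant,
    SimulationGrid,
    compile_variant,
)

__all__ = [
    "PriorSpec",
    "ParameterDensity",
    "FitResult",
    "FitOptions",
    "pack_parameters",
    "free_energy",
    "fit_dcm",
    "predicted_response",
]

#: prior variance of each latent parameter by kind
PRIOR_VARIANCES = {
    "A": 0.5,  # extrinsic log-gains (quantities of interest)
    "input_amp": 0.5,
    "obs": 0.5,
    "g": 1.0 / 16.0,  # intrinsic gain scalings (biophysical, tight)
}

LN2PI = float(np.log(2.0 * np.pi))


def _prior_variance(name: str) -> float:
    for prefix, var in PRIOR_VARIANCES.items():
        if name.startswith(prefix + "_") or name == prefix:
            return var
    raise KeyError(f"no prior variance rule for parameter {name!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Ordered latent parameterization of one model variant."""

    names: tuple[str, ...]
    mean: np.ndarray  # latent prior means (zeros)
    variance: np.ndarray  # latent prior variances

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(theta, dtype=float)))


def pack_parameters(variant: ModelVariant,
                    grid: SimulationGrid = SimulationGrid()) -> PriorSpec:
    """Deterministic latent parameterization for a variant.

    Pinned parameters (the null model's absent extrinsic connections,
    prior mean and variance zero) are excluded from the free set.
    """
    cv = compile_variant(variant, grid)
    names = tuple(cv.param_names)
    var = np.array([_prior_variance(n) for n in names])
    return PriorSpec(names=names, mean=np.zeros(len(names)), variance=var)


@dataclass
class ParameterDensity:
    """Gaussian posterior over latent parameters plus noise hyperparameter."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    lam: float = 0.0  # log observation-noise precision
    lam_var: float = 1.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def physical_means(self, prior_rates: dict[str, float] | None = None) -> dict[str, float]:
        rates = prior_rates or {}
        return {n: rates.get(n, 1.0) * float(np.exp(m))
                for n, m in zip(self.names, self.mean)}


@dataclass
class FitResult:
    posterior: ParameterDensity
    free_energy: float
    fitted: np.ndarray  # (n_sources, n_samples)
    residuals: np.ndarray
    trace: list[float] = field(default_factory=list)
    converged: bool = False
    variant_id: str = ""
    components: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 64
    tol: float = 1e-2  # free-energy improvement threshold (nats)
    patience: int = 4
    fd_step: float = 1e-3
    lambda_prior_var: float = 1.0
    max_halvings: int = 8


def _stack_data(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return np.atleast_2d(np.asarray(data, dtype=float))
    return np.vstack([np.asarray(d.amplitude, dtype=float) for d in data])


def _free_energy_terms(e: np.ndarray, lam: float, lam0: float, lam_var: float,
                       theta: np.ndarray, prior: PriorSpec,
                       post_cov: np.ndarray | None) -> dict[str, float]:
    n = e.size
    p = np.exp(lam)
    accuracy = -0.5 * p * float(e.ravel() @ e.ravel()) + 0.5 * n * (lam - LN2PI)
    d = theta - prior.mean
    complexity = 0.5 * float(d @ (d / prior.variance))
    if post_cov is not None:
        sign, logdet_q = np.linalg.slogdet(post_cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior covariance not positive definite")
        complexity -= 0.5 * (logdet_q - float(np.sum(np.log(prior.variance))) + len(theta))
        # entropy/cross terms: -KL(q||prior) for matched dimensions
        complexity += 0.5 * float(np.trace(np.diag(1.0 / prior.variance) @ post_cov))
    lam_curv = 0.5 * p * float(e.ravel() @ e.ravel()) + 1.0 / lam_var
    lam_post_var = 1.0 / lam_curv
    complexity_lam = (0.5 * (lam - lam0) ** 2 / lam_var
                      + 0.5 * (np.log(lam_var) - np.log(lam_post_var)) - 0.5
                      + 0.5 * lam_post_var / lam_var)
    return {
        "accuracy": accuracy,
        "complexity_theta": complexity,
        "complexity_lambda": complexity_lam,
        "total": accuracy - complexity - complexity_lam,
    }


def free_energy(data, variant: ModelVariant, q: ParameterDensity,
                grid: SimulationGrid = SimulationGrid(),
                lam0: float | None = None) -> dict[str, float]:
    """Laplace free energy of ``q`` for one data pair: accuracy - complexity.

    Returns the component breakdown; ``total`` is the free energy in nats.
    """
    Y = _stack_data(data)
    cv = compile_variant(variant, grid)
    prior = pack_parameters(variant, grid)
    if tuple(q.names) != prior.names:
        raise ValueError("parameter density does not match the variant's parameterization")
    pred = cv.simulate(prior.to_dict(q.mean))
    e = Y - pred
    if lam0 is None:
        lam0 = q.lam
    cov = q.cov if np.any(q.cov) else None
    return _free_energy_terms(e, q.lam, lam0, q.lam_var, q.mean, prior, cov)


def _jacobian(cv: CompiledVariant, prior: PriorSpec, theta: np.ndarray,
              h: float) -> np.ndarray:
    """Central finite-difference Jacobian of the stacked prediction."""
    cols = []
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        yp = cv.simulate(prior.to_dict(tp)).ravel()
        ym = cv.simulate(prior.to_dict(tm)).ravel()
        cols.append((yp - ym) / (2.0 * h))
    return np.column_stack(cols)


def _optimal_lambda(sse: float, n: int, lam0: float, lam_var: float,
                    lam_init: float) -> float:
    """Newton ascent on F(lambda) holding the residuals fixed."""
    lam = lam_init
    for _ in range(32):
        p = np.exp(lam)
        g = -0.5 * p * sse + 0.5 * n - (lam - lam0) / lam_var
        H = -0.5 * p * sse - 1.0 / lam_var
        step = -g / H
        step = np.clip(step, -4.0, 4.0)
        lam += step
        if abs(step) < 1e-8:
            break
    return float(lam)


def fit_dcm(data, variant: ModelVariant, options: FitOptions = FitOptions(),
            grid: SimulationGrid = SimulationGrid(),
            theta_init: np.ndarray | None = None) -> FitResult:
    """Invert one evoked-response pair under one model variant.

    ``data`` is either a pair of :class:`EvokedResponse` on the analysis
    grid or an array (n_sources, n_samples).  Deterministic given the
    data: initialization is at the prior mean unless ``theta_init`` is
    given.
    """
    Y = _stack_data(data)
    cv = compile_variant(variant, grid)
    prior = pack_parameters(variant, grid)
    if Y.shape[1] != len(grid.output_times):
        raise ValueError(
            f"data has {Y.shape[1]} samples; expected {len(grid.output_times)}")
    n = Y.size
    d = len(prior)
    y = Y.ravel()

    # noise hyperprior: prior guess is that noise is ~10% of data variance
    data_var = float(np.var(Y))
    lam0 = float(-np.log(max(0.1 * data_var, 1e-12)))
    lam = lam0

    theta = np.zeros(d) if theta_init is None else np.asarray(theta_init, dtype=float).copy()
    ip = 1.0 / prior.variance

    def predict(th):
        return cv.simulate(prior.to_dict(th)).ravel()

    pred = predict(theta)
    e = y - pred
    sse = float(e @ e)
    lam = _optimal_lambda(sse, n, lam0, options.lambda_prior_var, lam)

    def F_of(th, err, lm, cov):
        return _free_energy_terms(err, lm, lam0, options.lambda_prior_var,
                                  th, prior, cov)

    # posterior covariance at current expansion point
    def posterior_cov(J, lm):
        H = np.exp(lm) * (J.T @ J) + np.diag(ip)
        return np.linalg.inv(H)

    J = _jacobian(cv, prior, theta, options.fd_step)
    cov = posterior_cov(J, lam)
    terms = F_of(theta, e, lam, cov)
    F_best = terms["total"]
    trace = [F_best]
    nu = 1.0 / 256.0  # Levenberg damping
    stall = 0
    converged = False

    for _ in range(options.max_iter):
        p = np.exp(lam)
        grad = p * (J.T @ e) - ip * theta
        H = p * (J.T @ J) + np.diag(ip)
        accepted = False
        for _h in range(options.max_halvings):
            step = np.linalg.solve(H + nu * np.diag(np.diag(H)), grad)
            th_new = theta + step
            try:
                pred_new = predict(th_new)
            except Exception:
                nu *= 8.0
                continue
            e_new = y - pred_new
            sse_new = float(e_new @ e_new)
            lam_new = _optimal_lambda(sse_new, n, lam0, options.lambda_prior_var, lam)
            J_new = _jacobian(cv, prior, th_new, options.fd_step)
            cov_new = posterior_cov(J_new, lam_new)
            F_new = F_of(th_new, e_new, lam_new, cov_new)["total"]
            if np.isfinite(F_new) and F_new >= F_best:
                accepted = True
                break
            nu *= 8.0
        if not accepted:
            converged = True
            break
        improvement = F_new - F_best
        theta, e, lam, J, cov, F_best = th_new, e_new, lam_new, J_new, cov_new, F_new
        trace.append(F_best)
        nu = max(nu / 4.0, 1e-8)
        if improvement < options.tol:
            stall += 1
            if stall >= options.patience:
                converged = True
                break
        else:
            stall = 0

    if not np.isfinite(F_best):
        raise RuntimeError("non-finite free energy at termination")
    lam_curv = 0.5 * np.exp(lam) * float(e @ e) + 1.0 / options.lambda_prior_var
    posterior = ParameterDensity(names=prior.names, mean=theta, cov=cov, lam=lam,
                                 lam_var=1.0 / lam_curv)
    fitted = predict(theta).reshape(Y.shape)
    terms = F_of(theta, e, lam, cov)
    return FitResult(posterior=posterior, free_energy=F_best, fitted=fitted,
                     residuals=Y - fitted, trace=trace, converged=converged,
                     variant_id=variant.id, components=terms)


def predicted_response(fit: FitResult, variant: ModelVariant,
                       grid: SimulationGrid = SimulationGrid()) -> tuple[EvokedResponse, EvokedResponse]:
    """Forward simulation at the posterior mean."""
    cv = compile_variant(variant, grid)
    prior = pack_parameters(variant, grid)
    Y = cv.simulate(prior.to_dict(fit.posterior.mean))
    t = grid.output_times
    return tuple(EvokedResponse(region=nm, time_ms=t.copy(), amplitude=Y[i])
                 for i, nm in enumerate(cv.source_names))
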