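"""Hierarchical (parametric empirical Bayes) model over first-level fits.

Selected first-level parameters (by default the two extrinsic connection
log-gains) are regressed on a between-subject design matrix of group
mean, trial (extinction block) and freezing.  The second level is a
Gaussian random-effects model consuming the full first-level posteriors
(means and covariances), with a scalar random-effect precision estimated
by free-energy maximization.  Bayesian model reduction prunes covariate
effects without refitting and yields posterior probabilities of non-zero
effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .inversion import FitResult

__all__ = [
    "GroupDesign",
    "PEBResult",
    "ReducedModel",
    "build_design",
    "fit_peb",
    "bmr",
    "compare_reduced_models",
    "covariate_model_space",
    "posterior_prob_nonzero",
    "bayesian_model_average",
]

#: prior variance of each second-level coefficient
BETA_PRIOR_VAR = 0.5
#: effectively-zero prior variance used for masked-off coefficients
PINNED_VAR = 1e-8
#: log random-effect precision: prior mean and variance (broad)
GAMMA_PRIOR_MEAN = 0.0
GAMMA_PRIOR_VAR = 4.0


@dataclass
class GroupDesign:
    """Between-subject design: ones + mean-centered trial and freezing."""

    X: np.ndarray  # (n_rows, 3)
    rows: pd.DataFrame  # columns: subject, block
    columns: tuple[str, ...] = ("mean", "trial", "freezing")

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design matrix shape mismatch")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be constant (ones)")
        if self.X.shape[1] > 1 and \
                np.max(np.abs(self.X[:, 1:].sum(axis=0))) > 1e-8 * max(1, len(self.X)):
            raise ValueError("covariate columns must be mean-centered")


def build_design(covariates: pd.DataFrame) -> GroupDesign:
    """Design matrix from a (subject, block, freezing) covariate table.

    Rows are ordered subject-major, block-minor.  The trial covariate is
    the extinction block index; trial and freezing are mean-centered so
    the first regressor carries the group mean.
    """
    required = {"subject", "block", "freezing"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table is missing columns: {sorted(missing)}")
    bad = covariates[covariates[list(required)].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing covariate cells in rows: {bad.index.tolist()}")
    tab = covariates.sort_values(["subject", "block"], kind="stable").reset_index(drop=True)
    trial = tab["block"].to_numpy(dtype=float)
    freeze = tab["freezing"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(tab)),
        trial - trial.mean(),
        freeze - freeze.mean(),
    ])
    return GroupDesign(X=X, rows=tab[["subject", "block"]].copy())


@dataclass
class PEBResult:
    """Second-level coefficients over (parameter x design column)."""

    param_names: tuple[str, ...]  # selected first-level parameters (p)
    columns: tuple[str, ...]  # design columns (m)
    beta: np.ndarray  # (p, m) posterior means
    beta_cov: np.ndarray  # (p*m, p*m), row-major (param-major) flattening
    free_energy: float
    gamma: float  # log random-effect precision
    prior_var: np.ndarray  # (p*m,) second-level prior variances
    design: GroupDesign | None = None

    @property
    def n_coeff(self) -> int:
        return self.beta.size

    def flat_index(self, param: str, column: str) -> int:
        return self.param_names.index(param) * len(self.columns) + self.columns.index(column)

    def coefficient(self, param: str, column: str) -> tuple[float, float]:
        """Posterior (mean, sd) of one coefficient."""
        i = self.flat_index(param, column)
        return float(self.beta.ravel()[i]), float(np.sqrt(self.beta_cov[i, i]))


@dataclass
class ReducedModel:
    """On/off mask over second-level coefficients, (p, m) boolean."""

    mask: np.ndarray
    name: str = ""
    free_energy: float | None = None  # relative to the full model (delta F)
    beta: np.ndarray | None = None
    beta_cov: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def _select(fit: FitResult, selector: tuple[str, ...]):
    names = list(fit.posterior.names)
    try:
        idx = [names.index(s) for s in selector]
    except ValueError as err:
        raise ValueError(
            f"fit ({fit.variant_id}) lacks selected parameter: {err}") from None
    mu = fit.posterior.mean[idx]
    Sig = fit.posterior.cov[np.ix_(idx, idx)]
    return mu, Sig


def fit_peb(fits: list[FitResult], design: GroupDesign,
            selector: tuple[str, ...] | None = None) -> PEBResult:
    """Estimate second-level coefficients from first-level posteriors.

    Observation model per row i:  theta_i ~ N(X_i beta, Sigma_i + exp(-gamma) I),
    with Gaussian prior over beta and the scalar log-precision gamma
    estimated by maximizing the (penalized) model evidence.
    """
    if len(fits) != len(design.X):
        raise ValueError(f"{len(fits)} fits but {len(design.X)} design rows")
    if selector is None:
        selector = tuple(n for n in fits[0].posterior.names if n.startswith("A_"))
        if not selector:
            raise ValueError("no extrinsic parameters found to select")
    first = tuple(fits[0].posterior.names)
    for f in fits:
        if tuple(f.posterior.names) != first:
            raise ValueError("fits do not share a common parameterization")
    p = len(selector)
    m = design.X.shape[1]
    n = len(fits)
    mus, Sigs = zip(*(_select(f, selector) for f in fits))
    y = np.concatenate(mus)  # (n*p,)

    # sparse-free construction: D[i*p + j, j*m + mm] = X[i, mm]
    D = np.zeros((n * p, p * m))
    for j in range(p):
        D[j::p, j * m:(j + 1) * m] = design.X
    prior_var = np.full(p * m, BETA_PRIOR_VAR)

    def moments(gamma):
        rv = np.exp(-gamma)
        Vinv_blocks = [np.linalg.inv(S + rv * np.eye(p)) for S in Sigs]
        Vinv = np.zeros((n * p, n * p))
        for i, B in enumerate(Vinv_blocks):
            Vinv[i * p:(i + 1) * p, i * p:(i + 1) * p] = B
        H = D.T @ Vinv @ D + np.diag(1.0 / prior_var)
        cov = np.linalg.inv(H)
        mean = cov @ (D.T @ (Vinv @ y))
        # evidence: y ~ N(0, D Cb D' + V)
        logdet_V = -sum(np.linalg.slogdet(B)[1] for B in Vinv_blocks)
        sign, logdet_H = np.linalg.slogdet(H)
        quad = y @ (Vinv @ y) - mean @ H @ mean
        F = -0.5 * (n * p * np.log(2 * np.pi) + logdet_V + quad)
        F -= 0.5 * (np.sum(np.log(prior_var)) + logdet_H)
        F -= 0.5 * (gamma - GAMMA_PRIOR_MEAN) ** 2 / GAMMA_PRIOR_VAR
        return mean, cov, float(F)

    res = minimize_scalar(lambda g: -moments(g)[2], bounds=(-6.0, 8.0),
                          method="bounded", options={"xatol": 1e-4})
    gamma = float(res.x)
    mean, cov, F = moments(gamma)
    return PEBResult(param_names=tuple(selector), columns=design.columns,
                     beta=mean.reshape(p, m), beta_cov=cov, free_energy=F,
                     gamma=gamma, prior_var=prior_var, design=design)


def bmr(full: PEBResult, reduced: ReducedModel) -> ReducedModel:
    """Bayesian model reduction: re-evaluate evidence and posterior under a
    reduced prior (masked-off coefficients pinned at zero), analytically.
    """
    if reduced.mask.shape != full.beta.shape:
        raise ValueError("mask shape does not match the coefficient matrix")
    mask = reduced.mask.ravel()
    m0 = full.beta.ravel()
    P = np.linalg.inv(full.beta_cov)
    P0 = np.diag(1.0 / full.prior_var)
    var_r = np.where(mask, full.prior_var, PINNED_VAR)
    P0r = np.diag(1.0 / var_r)
    Pr = P + P0r - P0
    eig = np.linalg.eigvalsh((Pr + Pr.T) / 2)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError("reduced posterior precision is not PSD")
    Cr = np.linalg.inv(Pr)
    mr = Cr @ (P @ m0)
    dF = 0.5 * (np.linalg.slogdet(P)[1] - np.linalg.slogdet(Pr)[1]
                + np.linalg.slogdet(P0r)[1] - np.linalg.slogdet(P0)[1]
                - (m0 @ P @ m0 - mr @ Pr @ mr))
    return ReducedModel(mask=reduced.mask, name=reduced.name, free_energy=float(dF),
                        beta=mr.reshape(full.beta.shape), beta_cov=Cr)


def covariate_model_space(full: PEBResult) -> list[ReducedModel]:
    """All on/off combinations of the covariate columns (mean always on)."""
    p, m = full.beta.shape
    covs = list(range(1, m))
    models = []
    for keep in itertools.chain.from_iterable(
            itertools.combinations(covs, r) for r in range(len(covs), -1, -1)):
        mask = np.zeros((p, m), dtype=bool)
        mask[:, 0] = True
        for c in keep:
            mask[:, c] = True
        label = "+".join(full.columns[c] for c in keep) or "mean-only"
        models.append(ReducedModel(mask=mask, name=label))
    return models


def compare_reduced_models(full: PEBResult,
                           masks: list[ReducedModel]) -> tuple[list[ReducedModel], np.ndarray]:
    """Softmax model probabilities over reduced free energies.

    ``masks`` must include the full (all-on) model; returns the evaluated
    reduced models and their probabilities in matching order.
    """
    if not masks:
        raise ValueError("empty reduced-model list")
    if not any(rm.mask.all() for rm in masks):
        raise ValueError("the reduced-model set must include the full model")
    evaluated = [bmr(full, rm) for rm in masks]
    dF = np.array([rm.free_energy for rm in evaluated])
    w = np.exp(dF - dF.max())
    return evaluated, w / w.sum()


def bayesian_model_average(full: PEBResult,
                           models: list[ReducedModel] | None = None) -> PEBResult:
    """Average coefficient posteriors over the reduced-model set.

    Gaussian mixture moments weighted by reduced-model probability; the
    result reuses the PEBResult container (covariance keeps only the
    mixture's diagonal inflation on top of the weighted average).
    """
    if models is None:
        models = covariate_model_space(full)
    evaluated, w = compare_reduced_models(full, models)
    means = np.stack([rm.beta.ravel() for rm in evaluated])
    covs = np.stack([rm.beta_cov for rm in evaluated])
    mbar = w @ means
    cbar = np.einsum("k,kij->ij", w, covs)
    dev = means - mbar
    cbar += np.einsum("k,ki,kj->ij", w, dev, dev)
    return PEBResult(param_names=full.param_names, columns=full.columns,
                     beta=mbar.reshape(full.beta.shape), beta_cov=cbar,
                     free_energy=full.free_energy, gamma=full.gamma,
                     prior_var=full.prior_var, design=full.design)


def posterior_prob_nonzero(result: PEBResult, param: str, column: str) -> float:
    """Posterior mass of the coefficient's sign region containing its mean.

    0.5 for a zero-mean coefficient; the 0.95 decision threshold is a
    downstream reporting convention, never applied here.
    """
    mean, sd = result.coefficient(param, column)
    if sd == 0:
        return 1.0 if mean != 0 else 0.5
    return float(norm.cdf(abs(mean) / sd))
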