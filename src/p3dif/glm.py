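"""Three-level hierarchical linear-Gaussian model fitted by parametric empirical Bayes.

The model links a per-trial regressor (surprise in bits, or expectancy) to
measured trial-by-trial P300 amplitudes Y (μV):

    level 1:  Y_ℓ(n) = θ_ℓ + ϑ_ℓ·I_ℓ(n) + ε(1)          (per participant)
    level 2:  θ_ℓ = θ(2) + ε(2),  ϑ_ℓ = ϑ(2) + ε(2)      (group)
    level 3:  Θ(2) ~ N(0, λ(3) I)                         (shrinkage prior)

with isotropic level noises Σ(j) = λ(j)·I.  Collapsing the levels gives
Y ~ N(0, C) with

    C = λ(1)·I + λ(2)·X1 X1ᵀ + λ(3)·(X1 X2)(X1 X2)ᵀ,

a low-rank-plus-diagonal covariance that is handled through the
(2L+2)-dimensional precision of the stacked random effects, so fits cost
O(2NL·(2L+2)²) regardless of the number of trials.  The noise
hyperparameters are estimated by EM on the marginal likelihood of Y; the
log-evidence F = ln p(Y | model) at the optimum (the free-energy
approximation to the model evidence) feeds log-Bayes-factor model
comparison.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressorSet",
    "EMSettings",
    "HierarchicalFit",
    "build_design",
    "peb_fit",
    "log_bayes_factor",
    "goodness_of_fit",
    "LogBayesFactor",
]


def _fingerprint(Y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(Y, dtype=float).tobytes()).hexdigest()


@dataclass(frozen=True)
class RegressorSet:
    """Stacked data and design matrices of the hierarchical GLM.

    ``Y`` concatenates all participants' amplitude traces (2N trials each,
    both probability categories back to back); ``X1`` is block-diagonal
    with per-participant blocks [1, I_ℓ]; ``X2 = 1_L ⊗ I_2`` maps the two
    group parameters onto every participant's pair.
    """

    Y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    L: int
    n_trials: int  # trials per participant (2N)
    fingerprint: str = ""

    def __post_init__(self):
        if self.Y.size != self.L * self.n_trials:
            raise ValueError("Y length must equal L * n_trials")
        if self.X1.shape != (self.Y.size, 2 * self.L):
            raise ValueError("X1 must be (2NL, 2L)")
        if self.X2.shape != (2 * self.L, 2):
            raise ValueError("X2 must be (2L, 2)")
        if not self.fingerprint:
            object.__setattr__(self, "fingerprint", _fingerprint(self.Y))


def build_design(regressors, amplitudes) -> RegressorSet:
    """Assemble the stacked design from per-participant traces.

    Parameters
    ----------
    regressors : sequence of 1-d arrays
        Per-participant regressor traces (surprise or expectancy), all of
        the same length (2N when both probability categories are used).
    amplitudes : sequence of 1-d arrays
        Matching per-participant amplitude traces (μV).
    """
    regressors = [np.asarray(r, dtype=float).ravel() for r in regressors]
    amplitudes = [np.asarray(y, dtype=float).ravel() for y in amplitudes]
    if len(regressors) != len(amplitudes) or not regressors:
        raise ValueError("need equally many regressor and amplitude traces")
    n = regressors[0].size
    if any(r.size != n for r in regressors) or any(y.size != n for y in amplitudes):
        raise ValueError("all participants must share the same trial count")
    if not all(np.all(np.isfinite(r)) for r in regressors):
        raise ValueError("regressors must be finite")
    L = len(regressors)
    Y = np.concatenate(amplitudes)
    X1 = np.zeros((n * L, 2 * L))
    for ell, r in enumerate(regressors):
        rows = slice(ell * n, (ell + 1) * n)
        X1[rows, 2 * ell] = 1.0
        X1[rows, 2 * ell + 1] = r
    X2 = np.kron(np.ones((L, 1)), np.eye(2))
    return RegressorSet(Y=Y, X1=X1, X2=X2, L=L, n_trials=n)


@dataclass(frozen=True)
class EMSettings:
    """EM configuration for the hyperparameter estimation.

    ``lambda3`` defaults to 1e6·var(Y), an effectively flat shrinkage prior
    on the group parameters; set ``estimate_lambda3=True`` to include it in
    the EM updates instead.  ``fix_lambda1``/``fix_lambda2`` freeze a
    hyperparameter at a known value (no update), which turns the fit into
    plain Gaussian conditioning — useful for oracle comparisons.
    """

    max_iter: int = 256
    tol: float = 1e-6
    lambda1_init: float | None = None
    lambda2_init: float | None = None
    lambda3: float | None = None
    estimate_lambda3: bool = False
    fix_lambda1: float | None = None
    fix_lambda2: float | None = None


@dataclass
class HierarchicalFit:
    """Posterior summaries, hyperparameters and evidence of one model fit."""

    theta1_mean: np.ndarray      # (2L,) participant intercept/slope pairs
    theta1_cov: np.ndarray       # (2L, 2L)
    theta2_mean: np.ndarray      # (2,) group intercept and slope
    theta2_cov: np.ndarray       # (2, 2)
    lambdas: tuple               # (λ1, λ2, λ3)
    F: float                     # log-evidence ln p(Y | model), nats
    Yhat: np.ndarray             # fitted amplitudes X1 · E[Θ(1)]
    mse: float
    fve: float
    n_iter: int
    converged: bool
    F_history: np.ndarray
    fingerprint: str
    model: str = ""

    @property
    def theta2_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.theta2_cov))


def _conditional_moments(G, WtY, lam1, lam2, lam3, p2, p3):
    """Posterior moments of the stacked random effects b = (E(2), Θ(2)).

    Works through the eigendecomposition of B = D^{1/2} WᵀW D^{1/2}
    (D = blockdiag(λ2 I, λ3 I)), which stays numerically well-behaved in
    the extreme regimes the model visits routinely (λ1 → 0 for noise-free
    oracles, λ3 ~ 1e6·var(Y) for the flat group prior), where a direct
    Cholesky of the collapsed precision loses all significant digits.
    """
    sqrt_d = np.concatenate([np.full(p2, math.sqrt(lam2)),
                             np.full(p3, math.sqrt(lam3))])
    B = sqrt_d[:, None] * G * sqrt_d[None, :]
    evals, Q = np.linalg.eigh(B)
    evals = np.clip(evals, 0.0, None)
    denom = lam1 + evals
    u = Q.T @ (sqrt_d * WtY)
    mu = sqrt_d * (Q @ (u / denom))
    Sigma_b = (sqrt_d[:, None] * Q) @ ((lam1 / denom)[:, None]
                                       * (Q.T * sqrt_d[None, :]))
    return mu, Sigma_b, evals, denom, u


def _collapsed_logdensity(n_obs, r, lam1, denom, YtY, u):
    logdet_C = (n_obs - r) * math.log(lam1) + float(np.sum(np.log(denom)))
    quad = (YtY - float(np.sum(u ** 2 / denom))) / lam1
    return -0.5 * (n_obs * math.log(2.0 * math.pi) + logdet_C + quad)


def peb_fit(design: RegressorSet, config: EMSettings = EMSettings()) -> HierarchicalFit:
    """Fit the collapsed hierarchical model; EM over (λ1, λ2[, λ3]).

    Returns posterior means/covariances of participant and group
    parameters by Gaussian conditioning at the estimated hyperparameters,
    the log-evidence F, fitted values and goodness-of-fit.  Non-convergence
    within ``max_iter`` is flagged (``converged=False``) with a warning,
    never silently ignored.
    """
    Y, X1, X2 = design.Y, design.X1, design.X2
    L = design.L
    n_obs = Y.size
    var_y = float(np.var(Y))
    if var_y <= 0:
        raise ValueError("amplitudes have zero variance; nothing to fit")

    M = X1 @ X2
    W = np.hstack([X1, M])                    # (2NL, 2L+2)
    G = W.T @ W
    WtY = W.T @ Y
    YtY = float(Y @ Y)
    p2, p3 = 2 * L, 2

    lam1 = config.fix_lambda1 if config.fix_lambda1 is not None else \
        (config.lambda1_init if config.lambda1_init is not None else var_y)
    lam2 = config.fix_lambda2 if config.fix_lambda2 is not None else \
        (config.lambda2_init if config.lambda2_init is not None else var_y / 10.0)
    lam3 = config.lambda3 if config.lambda3 is not None else 1e6 * var_y

    lam1_floor = 1e-12 * var_y
    lam2_floor = 1e-12 * var_y

    F_hist = []
    converged = False
    mu = Sigma_b = None
    r = p2 + p3
    for it in range(1, config.max_iter + 1):
        if not np.all(np.isfinite([lam1, lam2, lam3])) or min(lam1, lam2, lam3) <= 0:
            raise np.linalg.LinAlgError(
                "hyperparameters left the feasible region; check for "
                "constant regressors or rescale Y")
        mu, Sigma_b, evals, denom, u = _conditional_moments(
            G, WtY, lam1, lam2, lam3, p2, p3)
        F = _collapsed_logdensity(n_obs, r, lam1, denom, YtY, u)
        F_hist.append(F)
        if it > 1 and abs(F - F_hist[-2]) <= config.tol * max(1.0, abs(F_hist[-2])):
            converged = True
            break

        # M-step: expected complete-data sufficient statistics
        if config.fix_lambda1 is None:
            e_resid = (YtY - 2.0 * mu @ WtY + mu @ G @ mu
                       + lam1 * float(np.sum(evals / denom)))
            lam1 = max(e_resid / n_obs, lam1_floor)
        if config.fix_lambda2 is None:
            mu2 = mu[:p2]
            lam2 = max((mu2 @ mu2 + np.trace(Sigma_b[:p2, :p2])) / p2, lam2_floor)
        if config.estimate_lambda3:
            mu3 = mu[p2:]
            lam3 = max((mu3 @ mu3 + np.trace(Sigma_b[p2:, p2:])) / p3, lam2_floor)

    if not converged and config.max_iter > 1:
        delta = abs(F_hist[-1] - F_hist[-2]) if len(F_hist) > 1 else float("inf")
        warnings.warn(f"EM did not converge within {config.max_iter} iterations "
                      f"(last |ΔF| = {delta:.3g})", RuntimeWarning, stacklevel=2)

    # posterior of Θ(1) = E(2) + X2 Θ(2) and of Θ(2)
    T = np.hstack([np.eye(p2), X2])           # (2L, 2L+2)
    theta1_mean = T @ mu
    theta1_cov = T @ Sigma_b @ T.T
    theta2_mean = mu[p2:]
    theta2_cov = Sigma_b[p2:, p2:]

    Yhat = X1 @ theta1_mean
    mse, fve = goodness_of_fit(Y, Yhat)
    return HierarchicalFit(
        theta1_mean=theta1_mean, theta1_cov=theta1_cov,
        theta2_mean=theta2_mean, theta2_cov=theta2_cov,
        lambdas=(float(lam1), float(lam2), float(lam3)),
        F=float(F_hist[-1]), Yhat=Yhat, mse=mse, fve=fve,
        n_iter=len(F_hist), converged=converged or config.max_iter == 1,
        F_history=np.asarray(F_hist), fingerprint=design.fingerprint,
    )


@dataclass(frozen=True)
class LogBayesFactor:
    value: float
    label: str | None

    def __float__(self):
        return self.value


def log_bayes_factor(fit_a: HierarchicalFit, fit_b: HierarchicalFit) -> LogBayesFactor:
    """ln BF(a, b) = F_a − F_b; values above 5 carry a 'very strong' label.

    Both fits must refer to the same data vector Y (checked by
    fingerprint): evidence differences across different data are
    meaningless.
    """
    if fit_a.fingerprint != fit_b.fingerprint:
        raise ValueError("log-Bayes factors require fits of the same data "
                         "(fingerprint mismatch)")
    value = float(fit_a.F - fit_b.F)
    return LogBayesFactor(value=value, label="very strong" if value > 5 else None)


def goodness_of_fit(Y, Yhat):
    """Pooled mean squared error and fraction of variance explained.

    FVE = 1 − SSE/SST with SST about the pooled mean of Y.  Zero variance
    in Y makes FVE undefined and raises.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Yhat = np.asarray(Yhat, dtype=float).ravel()
    if Y.size != Yhat.size:
        raise ValueError("Y and Yhat must have equal length")
    resid = Y - Yhat
    mse = float(np.mean(resid ** 2))
    sst = float(np.sum((Y - Y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("Y has zero variance; FVE undefined")
    fve = 1.0 - float(np.sum(resid ** 2)) / sst
    return mse, fve
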