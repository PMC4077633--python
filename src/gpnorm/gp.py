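"""Exact Gaussian-process regression with a squared-exponential ARD kernel.

This module is the numerical core of the normative-modeling toolkit: a
zero-mean GP prior over latent volume trajectories in covariate space, an
i.i.d. Gaussian noise model, type-II maximum likelihood (evidence
maximization) for the hyperparameters, and closed-form predictive
distributions whose z-scores form the Normative Probability Maps.

Model
-----
For one target (a voxel's volume, or a global tissue volume) with training
covariates ``X`` (n x m) and observations ``y``::

    y_i = g(x_i) + eps_i,     eps_i ~ N(0, sigma^2)
    g   ~ GP(0, k),           k(x_p, x_q) = a * exp(-1/2 * sum_k d_k^2 / l_k^2)

with amplitude ``a``, per-covariate length scales ``l_k`` (automatic
relevance determination: a large fitted length scale marks an irrelevant
covariate) and noise variance ``sigma^2``. Hyperparameters are selected by
maximizing the log marginal likelihood

    log p(y|X) = -1/2 y' C^-1 y - 1/2 log|C| - n/2 log(2*pi),  C = K + sigma^2 I

with analytic gradients in log-hyperparameter space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPHyperparams",
    "CovariateMatrix",
    "TrainedGP",
    "PredictiveResult",
    "FitConfig",
    "se_ard_kernel",
    "log_marginal_likelihood",
    "fit_gp",
    "gp_predict",
]

# Relative jitter schedule: start at 1e-8 * amplitude, escalate x10 on
# Cholesky failure up to 1e-2 * amplitude.
_JITTER_START = 1e-8
_JITTER_MAX = 1e-2


@dataclass
class GPHyperparams:
    """Kernel and noise hyperparameters of one GP model.

    Parameters
    ----------
    amplitude : float
        Signal variance ``a`` of the kernel (units of the squared target).
    length_scales : ndarray
        Per-covariate characteristic length scales, in standardized
        covariate units; one entry per column of the covariate matrix.
    noise_variance : float
        Observation-noise variance ``sigma^2``.
    """

    amplitude: float
    length_scales: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        self.length_scales = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        if self.amplitude <= 0 or self.noise_variance <= 0 or np.any(self.length_scales <= 0):
            raise ValueError("GP hyperparameters must be strictly positive")

    @property
    def n_dims(self) -> int:
        return self.length_scales.size

    def to_log_vector(self) -> np.ndarray:
        """Pack as [log a, log l_1..l_m, log sigma^2]."""
        return np.concatenate(
            [[np.log(self.amplitude)], np.log(self.length_scales), [np.log(self.noise_variance)]]
        )

    @classmethod
    def from_log_vector(cls, v: np.ndarray) -> "GPHyperparams":
        v = np.asarray(v, dtype=float)
        return cls(
            amplitude=float(np.exp(v[0])),
            length_scales=np.exp(v[1:-1]),
            noise_variance=float(np.exp(v[-1])),
        )

    def to_dict(self) -> dict:
        return {
            "amplitude": float(self.amplitude),
            "length_scales": [float(x) for x in self.length_scales],
            "noise_variance": float(self.noise_variance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPHyperparams":
        return cls(d["amplitude"], np.asarray(d["length_scales"], dtype=float), d["noise_variance"])


@dataclass
class CovariateMatrix:
    """Subject-by-covariate design matrix with training standardization.

    Columns are z-standardized with shift/scale recorded at training time;
    test matrices must always be standardized with the *training* statistics.
    Binary columns (sex, scanner field strength) are coded {0,1} and
    standardized like any other column so that ARD length scales are
    comparable across covariates.
    """

    values: np.ndarray
    column_names: list[str] = field(default_factory=list)
    shift: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix contains non-finite entries")
        if not self.column_names:
            self.column_names = [f"x{k}" for k in range(self.values.shape[1])]
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length does not match number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def fit_standardization(self) -> "CovariateMatrix":
        """Record per-column shift/scale from this (training) matrix."""
        self.shift = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        # constant columns get unit scale so they standardize to exactly zero
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def standardized(self) -> np.ndarray:
        if self.shift is None or self.scale is None:
            raise ValueError("standardization not fitted; call fit_standardization first")
        return (self.values - self.shift) / self.scale

    def standardize_like(self, other: "CovariateMatrix") -> np.ndarray:
        """Standardize with *other*'s (training) shift/scale — never our own."""
        if other.shift is None or other.scale is None:
            raise ValueError("training covariate matrix has no standardization")
        if self.m != other.m:
            raise ValueError(f"covariate dimension mismatch: {self.m} vs {other.m}")
        return (self.values - other.shift) / other.scale


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, CovariateMatrix):
        return np.atleast_2d(X.values)
    return np.atleast_2d(np.asarray(X, dtype=float))


def _sq_scaled_dists(Xp: np.ndarray, Xq: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis-style distances sum_k (xp_k - xq_k)^2 / l_k^2."""
    A = Xp / ls
    B = Xq / ls
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def se_ard_kernel(Xp, Xq, hyper: GPHyperparams) -> np.ndarray:
    """Squared-exponential ARD covariance between two covariate sets.

    Entry (p, q) is ``a * exp(-1/2 (x_p - x_q)' diag(l)^-2 (x_p - x_q))``.
    Both inputs must already be standardized with the same shift/scale.
    """
    Xp = _as_matrix(Xp)
    Xq = _as_matrix(Xq)
    if Xp.shape[1] != Xq.shape[1]:
        raise ValueError(f"covariate dimension mismatch: {Xp.shape[1]} vs {Xq.shape[1]}")
    if Xp.shape[1] != hyper.n_dims:
        raise ValueError(
            f"kernel has {hyper.n_dims} length scales but covariates have {Xp.shape[1]} columns"
        )
    return hyper.amplitude * np.exp(-0.5 * _sq_scaled_dists(Xp, Xq, hyper.length_scales))


def _chol_with_jitter(C: np.ndarray, amplitude: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky of C + jitter*I, escalating jitter until success."""
    jitter = _JITTER_START * amplitude
    while True:
        try:
            L = linalg.cholesky(C + jitter * np.eye(C.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            jitter *= 10.0
            if jitter > _JITTER_MAX * amplitude:
                raise linalg.LinAlgError(
                    "kernel matrix is ill-conditioned; Cholesky failed even with "
                    f"jitter {jitter / 10:.1e}"
                ) from None


def log_marginal_likelihood(
    hyper: GPHyperparams, X, y: np.ndarray, return_grad: bool = True
):
    """Log evidence of the GP and its gradient w.r.t. log-hyperparameters.

    Returns ``(lml, grad)`` where ``grad`` is ordered
    ``[d/dlog a, d/dlog l_1, ..., d/dlog l_m, d/dlog sigma^2]``; with
    ``return_grad=False`` returns only the scalar.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    K = se_ard_kernel(X, X, hyper)
    C = K + hyper.noise_variance * np.eye(n)
    L, _ = _chol_with_jitter(C, hyper.amplitude)
    alpha = linalg.cho_solve((L, True), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    if not return_grad:
        return lml

    # grad_j = 1/2 tr((alpha alpha' - C^-1) dC/dtheta_j); with W precomputed
    # each hyperparameter costs only an elementwise product.
    Cinv = linalg.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Cinv
    grad = np.empty(hyper.n_dims + 2)
    # dK/dlog a = K
    grad[0] = 0.5 * float(np.sum(W * K))
    # dK/dlog l_k = K * d_k^2 / l_k^2 (per-dimension squared distance)
    for k in range(hyper.n_dims):
        dk = X[:, k][:, None] - X[:, k][None, :]
        grad[1 + k] = 0.5 * float(np.sum(W * K * (dk * dk) / hyper.length_scales[k] ** 2))
    # dC/dlog sigma^2 = sigma^2 I
    grad[-1] = 0.5 * hyper.noise_variance * float(np.trace(W))
    return lml, grad


@dataclass
class FitConfig:
    """Settings for evidence maximization.

    ``n_restarts`` gradient-based searches are run from a data-driven
    initialization (log a = log var(y), log sigma^2 = log(var(y)/2),
    log l = 0) with N(0, 0.5^2) jitter on each restart's log-parameters.
    """

    n_restarts: int = 3
    max_iter: int = 200
    gtol: float = 1e-5


@dataclass
class TrainedGP:
    """A fitted GP: hyperparameters plus cached training factorization."""

    hyper: GPHyperparams
    train_covariates: CovariateMatrix
    train_targets: np.ndarray
    chol_factor: np.ndarray
    alpha: np.ndarray
    log_evidence: float
    target_mean: float = 0.0
    converged: bool = True

    @property
    def noise_variance(self) -> float:
        return self.hyper.noise_variance

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "hyper": self.hyper.to_dict(),
            "column_names": self.train_covariates.column_names,
            "covariate_values": self.train_covariates.values.tolist(),
            "covariate_shift": self.train_covariates.shift.tolist(),
            "covariate_scale": self.train_covariates.scale.tolist(),
            "train_targets": self.train_targets.tolist(),
            "target_mean": float(self.target_mean),
            "log_evidence": float(self.log_evidence),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedGP":
        hyper = GPHyperparams.from_dict(d["hyper"])
        Xc = CovariateMatrix(
            np.asarray(d["covariate_values"], dtype=float),
            list(d["column_names"]),
            shift=np.asarray(d["covariate_shift"], dtype=float),
            scale=np.asarray(d["covariate_scale"], dtype=float),
        )
        y = np.asarray(d["train_targets"], dtype=float)
        yc = y - d["target_mean"]
        Xs = Xc.standardized()
        C = se_ard_kernel(Xs, Xs, hyper) + hyper.noise_variance * np.eye(y.size)
        L, _ = _chol_with_jitter(C, hyper.amplitude)
        return cls(
            hyper=hyper,
            train_covariates=Xc,
            train_targets=y,
            chol_factor=L,
            alpha=linalg.cho_solve((L, True), yc),
            log_evidence=float(d["log_evidence"]),
            target_mean=float(d["target_mean"]),
            converged=bool(d["converged"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TrainedGP":
        return cls.from_dict(json.loads(s))


@dataclass
class PredictiveResult:
    """Predictive distribution for test rows, optionally with z-scores.

    ``z`` follows the atrophy sign convention: negative z means less
    volume than predicted.
    """

    mean: np.ndarray
    latent_variance: np.ndarray
    observation_variance: np.ndarray
    z: np.ndarray | None = None


def fit_gp(X, y: np.ndarray, config: FitConfig | None = None, seed: int = 0) -> TrainedGP:
    """Fit GP hyperparameters by multi-restart evidence maximization.

    Covariates are z-standardized per column (training statistics stored on
    the returned model); targets are centered by their training mean, which
    is restored at prediction time (the GP prior mean is fixed at zero).
    Deterministic given ``seed``; restart ``r`` uses ``seed + r``.
    """
    config = config or FitConfig()
    if isinstance(X, CovariateMatrix):
        Xc = CovariateMatrix(X.values.copy(), list(X.column_names))
    else:
        Xc = CovariateMatrix(np.atleast_2d(np.asarray(X, dtype=float)))
    if Xc.n < 2:
        raise ValueError("GP training requires at least 2 subjects")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != Xc.n:
        raise ValueError("length of y does not match number of covariate rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("training targets contain non-finite values")

    Xc.fit_standardization()
    Xs = Xc.standardized()
    y_mean = float(y.mean())
    yc = y - y_mean

    var_y = max(float(yc.var()), 1e-12)
    m = Xc.m
    base = np.concatenate([[np.log(var_y)], np.zeros(m), [np.log(var_y / 2.0)]])

    def objective(v):
        hyper = GPHyperparams.from_log_vector(v)
        try:
            lml, grad = log_marginal_likelihood(hyper, Xs, yc)
        except linalg.LinAlgError:
            return 1e25, np.zeros_like(v)
        return -lml, -grad

    best = None
    any_converged = False
    for r in range(max(config.n_restarts, 1)):
        if r == 0:
            v0 = base.copy()
        else:
            rng = np.random.default_rng(seed + r)
            v0 = base + rng.normal(0.0, 0.5, size=base.size)
        res = optimize.minimize(
            objective,
            v0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "gtol": config.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    hyper = GPHyperparams.from_log_vector(best.x)
    C = se_ard_kernel(Xs, Xs, hyper) + hyper.noise_variance * np.eye(Xc.n)
    L, _ = _chol_with_jitter(C, hyper.amplitude)
    return TrainedGP(
        hyper=hyper,
        train_covariates=Xc,
        train_targets=y,
        chol_factor=L,
        alpha=linalg.cho_solve((L, True), yc),
        log_evidence=-float(best.fun),
        target_mean=y_mean,
        converged=any_converged,
    )


def gp_predict(model: TrainedGP, Xstar, ystar: np.ndarray | None = None) -> PredictiveResult:
    """Closed-form GP predictive distribution at new covariate rows.

    ``Xstar`` is given in raw covariate units and standardized internally
    with the training shift/scale. ``mean`` is the predicted observation
    mean; ``observation_variance`` is the latent posterior variance plus the
    noise variance u^2; with ``ystar`` supplied, ``z = (y* - mean) / u``.
    """
    if isinstance(Xstar, CovariateMatrix):
        Xstar = Xstar.values
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    Xs_star = CovariateMatrix(Xstar).standardize_like(model.train_covariates)
    Xs_train = model.train_covariates.standardized()

    Ks = se_ard_kernel(Xs_star, Xs_train, model.hyper)  # q x n
    mean = Ks @ model.alpha + model.target_mean
    # latent variance: k(x*,x*) - k(x*,X) C^-1 k(X,x*), via the cached factor
    v = linalg.solve_triangular(model.chol_factor, Ks.T, lower=True)
    latent_var = model.hyper.amplitude - np.sum(v * v, axis=0)
    np.maximum(latent_var, 0.0, out=latent_var)
    obs_var = latent_var + model.hyper.noise_variance
    z = None
    if ystar is not None:
        ystar = np.asarray(ystar, dtype=float).ravel()
        z = (ystar - mean) / np.sqrt(obs_var)
    return PredictiveResult(
        mean=mean, latent_variance=latent_var, observation_variance=obs_var, z=z
    )
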