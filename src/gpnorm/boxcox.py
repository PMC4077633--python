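"""Voxelwise Box-Cox power transformation with ML lambda selection.

Modulated gray-matter volume data are typically positively skewed, which
biases Gaussian single-case inference. Each voxel's observations are
therefore passed through the Box-Cox transform

    f_lambda(y) = (y^lambda - 1) / lambda      (lambda != 0)
                = log y                        (lambda == 0)

with lambda chosen per voxel by maximizing the profile log-likelihood

    L(lambda) = -(n/2) log sigma_lambda^2 + (lambda - 1) * sum(log y)

where sigma_lambda^2 is the ML residual variance of the transformed data
about its mean (the transform is a separate modeling step before the GP,
so an intercept-only residual model is used) and the second term is the
log-Jacobian. To keep the voxelwise scaling comparable to the raw data,
the transformed values are rescaled by the first-order Taylor factor
f_lambda'(mu) = mu^(lambda-1) around the training mean mu, so that
Var(y) ~ Var(f_lambda(y) / f_lambda'(mu)).

Lambda, mu and the rescale factor are estimated on training data only and
reused unchanged for test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BoxCoxModel",
    "NormalityReport",
    "boxcox_forward",
    "boxcox_inverse",
    "boxcox_loglik",
    "fit_lambda",
    "apply_rescaled",
    "normality_report",
]

LAMBDA_BOUNDS = (-3.0, 3.0)
NEG_INF = -np.inf


def _check_positive(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive data; apply the configured "
            "positive shift (e.g. epsilon=1e-4) before transforming"
        )
    return y


def boxcox_forward(y, lambda_: float) -> np.ndarray:
    """(y^lambda - 1)/lambda, or log y at lambda = 0; continuous in lambda."""
    y = _check_positive(y)
    if lambda_ == 0.0:
        return np.log(y)
    # expm1 keeps the small-lambda limit exact (continuity at lambda = 0)
    return np.expm1(lambda_ * np.log(y)) / lambda_


def boxcox_inverse(z, lambda_: float) -> np.ndarray:
    """Inverse of :func:`boxcox_forward` on its valid domain."""
    z = np.asarray(z, dtype=float)
    if lambda_ == 0.0:
        return np.exp(z)
    return np.exp(np.log1p(lambda_ * z) / lambda_)


def boxcox_loglik(lambda_: float, y) -> float:
    """Profile log-likelihood of lambda (intercept-only residual model).

    Returns ``-inf`` when the transformed data are exactly constant
    (zero residual variance).
    """
    y = _check_positive(y)
    if y.size < 3:
        raise ValueError("Box-Cox likelihood needs at least 3 observations")
    z = boxcox_forward(y, lambda_)
    var = float(np.var(z))  # ML (1/n) variance about the mean
    if var <= 0.0 or not np.isfinite(var):
        return NEG_INF
    n = y.size
    return -0.5 * n * np.log(var) + (lambda_ - 1.0) * float(np.sum(np.log(y)))


@dataclass
class BoxCoxModel:
    """Fitted per-voxel transform: power, training mean, Taylor rescale.

    ``scale_`` is f_lambda'(mu) = mu^(lambda-1); dividing the transformed
    data by it restores the raw-data variance to first order. ``shift``
    records any positive offset added before the transform (zeros occur
    inside brain masks), applied identically at train and test time.
    ``at_bound`` flags an optimizer solution on the search boundary.
    """

    lambda_: float
    mean_: float
    scale_: float
    shift: float = 0.0
    at_bound: bool = False

    def transform(self, y) -> np.ndarray:
        return apply_rescaled(self, y)

    def inverse_transform(self, z) -> np.ndarray:
        return boxcox_inverse(np.asarray(z, dtype=float) * self.scale_, self.lambda_) - self.shift

    def to_dict(self) -> dict:
        return {
            "lambda": float(self.lambda_),
            "mean": float(self.mean_),
            "scale": float(self.scale_),
            "shift": float(self.shift),
            "at_bound": bool(self.at_bound),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoxCoxModel":
        return cls(d["lambda"], d["mean"], d["scale"], d.get("shift", 0.0), d.get("at_bound", False))


def fit_lambda(y, shift: float = 0.0) -> BoxCoxModel:
    """ML estimate of lambda by bounded scalar search over [-3, 3].

    ``shift`` is added to the data first (and stored) so that strictly
    positive input is guaranteed for e.g. masked volume data with zeros.
    """
    y = np.asarray(y, dtype=float).ravel() + shift
    y = _check_positive(y)
    res = optimize.minimize_scalar(
        lambda lam: -boxcox_loglik(lam, y),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    at_bound = min(lam - LAMBDA_BOUNDS[0], LAMBDA_BOUNDS[1] - lam) < 1e-4
    mu = float(np.mean(y))
    return BoxCoxModel(
        lambda_=lam, mean_=mu, scale_=mu ** (lam - 1.0), shift=shift, at_bound=at_bound
    )


def apply_rescaled(model: BoxCoxModel, y) -> np.ndarray:
    """Transform with the trained lambda and divide by f_lambda'(mu).

    At lambda = 1 this is exactly y - 1 (variance preserved); in general
    the output variance matches the input variance to first order. Strictly
    monotone increasing in y for every lambda.
    """
    y = np.asarray(y, dtype=float).ravel() + model.shift
    if model.shift > 0:
        # applying a trained shift to new data: clip to the valid domain
        # rather than reject (test subjects may undershoot the training min)
        y = np.maximum(y, 1e-12)
    return boxcox_forward(y, model.lambda_) / model.scale_


@dataclass
class NormalityReport:
    """Residual-normality diagnostics for one voxel.

    ``kurtosis`` is the plain fourth standardized moment (normal => ~3,
    not excess); ``qq_correlation`` is the correlation between sorted
    residuals and standard-normal plotting positions.
    """

    qq_correlation: float
    skewness: float
    kurtosis: float


def normality_report(residuals) -> NormalityReport:
    """Q-Q correlation, skewness and kurtosis of a residual vector."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 4:
        raise ValueError("normality diagnostics need at least 4 residuals")
    n = r.size
    # Blom plotting positions, standard for normal Q-Q plots
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq = float(np.corrcoef(np.sort(r), theoretical)[0, 1])
    return NormalityReport(
        qq_correlation=qq,
        skewness=float(stats.skew(r)),
        kurtosis=float(stats.kurtosis(r, fisher=False)),
    )
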