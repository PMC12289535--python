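"""Regression backends: Gaussian-process default plus a pluggable contract.

The default regressor is a Gaussian process with covariance

    k(x_i, x_j) = theta0 * exp(-(theta1 / 2) * ||x_i - x_j||^2) + theta2,

i.e. a signal-variance-scaled RBF kernel with an additive constant, plus a
jointly fitted observation-noise variance for numerical stability on noisy
data.  Hyperparameters are optimised by marginal-likelihood maximisation
(scikit-learn) from deterministic seeded initial values.  Features and
target are autoscaled inside each fit, from training data only, so the
single isotropic length-scale is meaningful for multi-descriptor inputs.

Any object implementing :class:`RegressionBackend` (``fit(X, y) -> handle``
where the handle has ``predict(X)``) can replace the default — the tests
use an exactly solvable ordinary-least-squares backend as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression

from .exceptions import FitFailureError, InputError

__all__ = [
    "KernelParams",
    "kernel_value",
    "BackendConfig",
    "RegressorHandle",
    "GPRBackend",
    "OLSBackend",
    "make_backend",
    "fit_regressor",
    "predict",
    "MIN_TRAIN_SAMPLES",
]

#: Minimum training-set size for the default (GPR) backend.  OLS accepts
#: two samples — a straight line is determined by two points — which the
#: leave-one-out oracle tests on tiny datasets rely on.
MIN_TRAIN_SAMPLES = 3
MIN_TRAIN_SAMPLES_OLS = 2


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the RBF-plus-constant kernel.

    ``theta0`` scales the signal variance, ``theta1`` is the inverse squared
    length-scale factor, and ``theta2`` is the additive constant.  At zero
    distance the kernel evaluates to ``theta0 + theta2``.
    """

    theta0: float
    theta1: float
    theta2: float

    def __post_init__(self) -> None:
        for name in ("theta0", "theta1", "theta2"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InputError(f"{name} must be finite, got {v}")
        if self.theta0 <= 0:
            raise InputError(f"theta0 must be > 0, got {self.theta0}")
        if self.theta1 <= 0:
            raise InputError(f"theta1 must be > 0, got {self.theta1}")
        if self.theta2 < 0:
            raise InputError(f"theta2 must be >= 0, got {self.theta2}")

    @property
    def length_scale(self) -> float:
        """RBF length-scale ``l`` with ``theta1 = 1 / l**2``."""
        return 1.0 / np.sqrt(self.theta1)


def kernel_value(params: KernelParams, xi, xj) -> float:
    """Evaluate the kernel for one pair of feature vectors.

    Returns ``theta0 * exp(-(theta1/2) * ||xi - xj||^2) + theta2``; symmetric
    in its two arguments by construction.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    xj = np.atleast_1d(np.asarray(xj, dtype=float))
    if xi.shape != xj.shape:
        raise InputError(
            f"dimension mismatch: xi has shape {xi.shape}, xj {xj.shape}"
        )
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise InputError("kernel inputs must be finite")
    sq = float(np.sum((xi - xj) ** 2))
    return float(params.theta0 * np.exp(-0.5 * params.theta1 * sq) + params.theta2)


@dataclass(frozen=True)
class BackendConfig:
    """Settings selecting and tuning a regression backend.

    Parameters
    ----------
    backend : {"gpr", "ols"}
        Default Gaussian process, or ordinary least squares (used mostly as
        an exactly verifiable oracle).
    n_restarts : int
        Total number of optimizer starts for GPR hyperparameter selection
        (first start from the current kernel parameters, the rest from
        seeded random draws within the bounds).
    seed : int
        Seed for the restart draws; makes fits deterministic.
    noise_bounds : (float, float)
        Bounds for the jointly fitted observation-noise variance.
    """

    backend: str = "gpr"
    n_restarts: int = 10
    seed: int = 0
    noise_bounds: tuple[float, float] = (1e-8, 1e2)

    def __post_init__(self) -> None:
        if self.backend not in ("gpr", "ols"):
            raise InputError(f"unknown backend {self.backend!r}; use 'gpr' or 'ols'")
        if self.n_restarts < 1:
            raise InputError("n_restarts must be >= 1")
        lo, hi = self.noise_bounds
        if not (0 < lo <= hi):
            raise InputError(f"invalid noise bounds {self.noise_bounds}")

    def with_seed(self, seed: int) -> "BackendConfig":
        return replace(self, seed=int(seed))

    def key(self) -> tuple:
        """Hashable identity for caching."""
        return (self.backend, self.n_restarts, self.seed, self.noise_bounds)


@dataclass
class RegressorHandle:
    """A fitted regressor: scaling parameters plus the backend's estimator.

    Scaling parameters are computed from the training data only.  ``predict``
    accepts feature matrices of the fitted dimensionality and returns one
    finite prediction per row, deterministically.
    """

    backend_name: str
    n_features: int
    x_center: np.ndarray
    x_scale: np.ndarray
    estimator: object
    kernel_params: KernelParams | None = None
    train_shape: tuple[int, int] = (0, 0)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.shape[1] != self.n_features:
            raise InputError(
                f"handle fitted on {self.n_features} features, "
                f"got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise InputError("prediction inputs must be finite")
        Xs = (X - self.x_center) / self.x_scale
        yhat = np.asarray(self.estimator.predict(Xs), dtype=float).ravel()
        if not np.all(np.isfinite(yhat)):
            raise FitFailureError(
                f"{self.backend_name} produced non-finite predictions"
            )
        return yhat


def _autoscale_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # zero-variance columns are centered but not scaled
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0.0] = 1.0
    return center, scale


def _validate_training(X, y, min_samples: int = MIN_TRAIN_SAMPLES
                       ) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise InputError(f"{X.shape[0]} feature rows but {y.shape[0]} targets")
    if X.shape[0] < min_samples:
        raise InputError(
            f"need at least {min_samples} training samples, got {X.shape[0]}"
        )
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise InputError("training data must be finite")
    return X, y


class GPRBackend:
    """Gaussian-process regression with the RBF-plus-constant kernel."""

    name = "gpr"
    min_train_samples = MIN_TRAIN_SAMPLES

    def __init__(self, config: BackendConfig | None = None) -> None:
        self.config = config or BackendConfig()

    def _kernel(self):
        return (
            ConstantKernel(1.0, (1e-5, 1e5)) * RBF(1.0, (1e-3, 1e3))
            + ConstantKernel(1.0, (1e-8, 1e5))
            + WhiteKernel(1e-6, self.config.noise_bounds)
        )

    def fit(self, X, y) -> RegressorHandle:
        X, y = _validate_training(X, y)
        center, scale = _autoscale_params(X)
        Xs = (X - center) / scale
        est = GaussianProcessRegressor(
            kernel=self._kernel(),
            n_restarts_optimizer=self.config.n_restarts - 1,
            normalize_y=True,  # centers and unit-scales y per training fit
            random_state=self.config.seed,
        )
        try:
            with warnings.catch_warnings():
                # hyperparameters pinned at a bound are routine on clean data
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xs, y)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitFailureError(f"GPR fit failed: {exc}") from exc
        k = est.kernel_
        theta0 = float(k.k1.k1.k1.constant_value)
        ell = float(k.k1.k1.k2.length_scale)
        theta2 = float(k.k1.k2.constant_value)
        params = KernelParams(theta0=theta0, theta1=1.0 / ell**2, theta2=theta2)
        return RegressorHandle(
            backend_name=self.name,
            n_features=X.shape[1],
            x_center=center,
            x_scale=scale,
            estimator=est,
            kernel_params=params,
            train_shape=X.shape,
        )


class OLSBackend:
    """Ordinary least squares with intercept; exactly solvable oracle."""

    name = "ols"
    min_train_samples = MIN_TRAIN_SAMPLES_OLS

    def __init__(self, config: BackendConfig | None = None) -> None:
        self.config = config or BackendConfig(backend="ols")

    def fit(self, X, y) -> RegressorHandle:
        X, y = _validate_training(X, y, self.min_train_samples)
        center, scale = _autoscale_params(X)
        est = LinearRegression()
        est.fit((X - center) / scale, y)
        if not np.all(np.isfinite(est.coef_)):
            raise FitFailureError("OLS produced non-finite coefficients")
        return RegressorHandle(
            backend_name=self.name,
            n_features=X.shape[1],
            x_center=center,
            x_scale=scale,
            estimator=est,
            train_shape=X.shape,
        )


def make_backend(config: BackendConfig):
    """Instantiate the backend selected by ``config``."""
    if config.backend == "gpr":
        return GPRBackend(config)
    return OLSBackend(config)


def fit_regressor(X, y, config: BackendConfig | None = None) -> RegressorHandle:
    """Fit the configured backend on training data; functional facade."""
    return make_backend(config or BackendConfig()).fit(X, y)


def predict(handle: RegressorHandle, X) -> np.ndarray:
    """Predict with a fitted handle; functional facade."""
    return handle.predict(X)
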