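"""Spatial interpolators for cluster-level proportions.

Two main model classes, plus baselines:

* :class:`SpatialGPModel` — a hierarchical spatial regression
  ``y(s) = X(s)'beta + v(s) + e(s)`` with ``v`` a zero-mean stationary
  Gaussian process with Matern nu=1 covariance (the field defined by the
  SPDE operator ``(k^2 - Laplacian)`` in two dimensions) and ``e`` i.i.d.
  Gaussian noise.  Hyperparameters are estimated by maximizing the log
  marginal likelihood with beta profiled out by generalized least squares
  (empirical Bayes); the predictive standard deviation therefore omits
  hyperparameter uncertainty.  The Gaussian likelihood on proportions
  mirrors the mean-squared-error-centric treatment under which the models
  are compared.

* :class:`AnnModel` — a single-hidden-layer feed-forward network written
  directly from its defining equations: each node computes the weighted sum
  of incoming signals plus a bias, ``s_j = sum_i W_ij x_i + b_j``, and
  passes it through the logistic activation ``y = 1 / (1 + exp(-s_j))``, so
  the output is bounded in (0, 1) like a proportion.  Training is
  full-batch gradient descent with momentum on squared error; hidden size
  and learning rate are tuned by repeated random 70/30 sub-sampling.

* Trivial mean and ordinary linear baselines anchoring the pseudo-R2 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from sklearn.linear_model import LinearRegression

from .covariates import DesignMatrix

__all__ = [
    "matern_cov",
    "SpatialGPModel",
    "GPConfig",
    "fit_gp",
    "gp_predict",
    "gp_log_marginal_likelihood",
    "AnnModel",
    "AnnSearchSpace",
    "ann_forward",
    "fit_ann",
    "fit_ann_ensemble",
    "ann_predict",
    "MeanModel",
    "LinearModel",
    "fit_mean_baseline",
    "fit_linear",
]

logger = logging.getLogger(__name__)

_JITTER = 1e-10


# ---------------------------------------------------------------------------
# Matern covariance (nu = 1)


def matern_cov(distance, sigma_v2: float, range_m: float):
    """Matern nu=1 covariance ``sigma_v2 * (kappa d) K_1(kappa d)``.

    ``kappa = sqrt(8)/range_m`` so correlation decays to ~0.14 at the
    practical range.  The value at d=0 is exactly ``sigma_v2``.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    kappa = np.sqrt(8.0) / range_m
    x = kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        c = np.where(x > 0, x * special.kv(1, np.where(x > 0, x, 1.0)), 1.0)
    c = np.where(np.isfinite(c), c, 0.0)  # kv underflows to 0 at huge x
    out = sigma_v2 * np.where(x == 0, 1.0, c)
    if np.ndim(distance) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Spatial Gaussian-process regression


@dataclass
class GPConfig:
    """Settings for hyperparameter estimation.

    ``fixed_params`` pins (sigma_v2, range_m, sigma_e2) and skips the
    optimization, which is useful for oracle comparisons.
    """

    n_starts: int = 3
    maxiter: int = 200
    fixed_params: tuple[float, float, float] | None = None
    include_nugget_in_sd: bool = False


@dataclass
class SpatialGPModel:
    beta: np.ndarray
    sigma_v2: float
    range_m: float
    sigma_e2: float
    alpha_smoothness: float = 2.0  # SPDE operator power; nu = alpha - d/2 = 1
    covariate_names: list[str] = field(default_factory=list)
    train_coords: np.ndarray | None = None
    _chol: tuple | None = None
    _resid_solve: np.ndarray | None = None  # Sigma^{-1} (y - X beta)
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None
    log_marginal_likelihood: float = np.nan

    def __post_init__(self) -> None:
        if self.sigma_v2 < 0 or self.sigma_e2 <= 0 or self.range_m <= 0:
            raise ValueError("invalid hyperparameters")

    def standardize(self, X_raw: np.ndarray) -> np.ndarray:
        X_raw = np.asarray(X_raw, dtype=float)
        if self.col_means is None:
            return X_raw
        return (X_raw - self.col_means) / self.col_sds


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def gp_log_marginal_likelihood(
    params: tuple[float, float, float],
    coords: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    return_beta: bool = False,
):
    """Profile log marginal likelihood of (sigma_v2, range_m, sigma_e2).

    beta is profiled out by generalized least squares at the given
    hyperparameters; the returned value is the Gaussian log density of the
    residuals under ``Sigma = sigma_v2 M(D) + sigma_e2 I``.
    """
    sigma_v2, range_m, sigma_e2 = params
    n = len(y)
    D = cdist(coords, coords)
    K = matern_cov(D, sigma_v2, range_m) + (sigma_e2 + _JITTER) * np.eye(n)
    Xd = _design_with_intercept(X)
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return (-np.inf, None) if return_beta else -np.inf
    Ki_X = cho_solve((c, low), Xd)
    Ki_y = cho_solve((c, low), y)
    XtKiX = Xd.T @ Ki_X
    try:
        beta = np.linalg.solve(XtKiX, Xd.T @ Ki_y)
    except np.linalg.LinAlgError:
        return (-np.inf, None) if return_beta else -np.inf
    resid = y - Xd @ beta
    quad = resid @ cho_solve((c, low), resid)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ll = -0.5 * (quad + logdet + n * np.log(2 * np.pi))
    if return_beta:
        return ll, beta
    return ll


def fit_gp(
    design: DesignMatrix,
    coords: np.ndarray,
    y: np.ndarray,
    config: GPConfig | None = None,
) -> SpatialGPModel:
    """Fit the spatial regression by maximum marginal likelihood.

    Hyperparameters are optimized on the log scale by bounded L-BFGS from
    several data-driven starting points; beta is the GLS solution at the
    optimum.  ``coords`` are the reported (displaced) cluster locations.
    """
    config = config or GPConfig()
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    X = design.values
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 clusters to fit the spatial model")
    if coords.shape != (n, 2):
        raise ValueError("coords must be an (n, 2) array matching y")

    if config.fixed_params is not None:
        ll, beta = gp_log_marginal_likelihood(config.fixed_params, coords, X, y, return_beta=True)
        sigma_v2, range_m, sigma_e2 = config.fixed_params
        return _finalize_gp(design, coords, X, y, beta, sigma_v2, range_m, sigma_e2, ll, config)

    # data-driven scales for starts and bounds
    ols = LinearRegression().fit(X, y)
    resid_var = max(np.var(y - ols.predict(X)), 1e-8)
    span = max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0)

    def nll(log_params):
        p = np.exp(log_params)
        val = gp_log_marginal_likelihood((p[0], p[1], p[2]), coords, X, y)
        return -val if np.isfinite(val) else 1e12

    bounds = [
        (np.log(resid_var * 1e-6), np.log(resid_var * 100)),
        (np.log(span * 1e-3), np.log(span * 10)),
        (np.log(resid_var * 1e-6), np.log(resid_var * 100)),
    ]
    starts = [
        np.log([0.5 * resid_var, 0.2 * span, 0.5 * resid_var]),
        np.log([0.9 * resid_var, 0.05 * span, 0.1 * resid_var]),
        np.log([0.1 * resid_var, 0.5 * span, 0.9 * resid_var]),
        np.log([resid_var, 0.1 * span, resid_var]),
    ][: max(config.n_starts, 1)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": config.maxiter}
        )
        if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "marginal likelihood non-finite at every start; consider rescaling "
            "coordinates or responses"
        )
    sigma_v2, range_m, sigma_e2 = np.exp(best.x)
    ll, beta = gp_log_marginal_likelihood((sigma_v2, range_m, sigma_e2), coords, X, y, return_beta=True)
    return _finalize_gp(design, coords, X, y, beta, sigma_v2, range_m, sigma_e2, ll, config)


def _finalize_gp(design, coords, X, y, beta, sigma_v2, range_m, sigma_e2, ll, config):
    n = len(y)
    D = cdist(coords, coords)
    K = matern_cov(D, sigma_v2, range_m) + (sigma_e2 + _JITTER) * np.eye(n)
    c, low = cho_factor(K, lower=True)
    resid = y - _design_with_intercept(X) @ beta
    return SpatialGPModel(
        beta=np.asarray(beta, dtype=float),
        sigma_v2=float(sigma_v2),
        range_m=float(range_m),
        sigma_e2=float(max(sigma_e2, _JITTER)),
        covariate_names=list(design.covariate_names),
        train_coords=coords,
        _chol=(c, low),
        _resid_solve=cho_solve((c, low), resid),
        col_means=design.col_means,
        col_sds=design.col_sds,
        log_marginal_likelihood=float(ll),
    )


def gp_predict(
    model: SpatialGPModel,
    X_new: np.ndarray,
    coords_new: np.ndarray,
    include_nugget: bool = False,
    clamp: bool = True,
    standardized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional predictive mean and standard deviation at new sites.

    ``standardized=False`` applies the stored column scaling to raw
    covariate values first.  The default standard deviation is that of the
    latent smooth surface; ``include_nugget`` adds the site-level noise
    variance.  Means are clamped to [0, 1] for reporting.
    """
    X_new = np.asarray(X_new, dtype=float)
    coords_new = np.asarray(coords_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(model.beta) - 1:
        raise ValueError(
            f"X_new must have {len(model.beta) - 1} columns, got shape {X_new.shape}"
        )
    if not standardized:
        X_new = model.standardize(X_new)
    Xd = _design_with_intercept(X_new)
    trend = Xd @ model.beta
    if model.train_coords is None:
        mean, var = trend, np.full(len(X_new), model.sigma_v2)
    else:
        Kstar = matern_cov(cdist(coords_new, model.train_coords), model.sigma_v2, model.range_m)
        mean = trend + Kstar @ model._resid_solve
        c, lowf = model._chol
        L = np.tril(c) if lowf else np.triu(c).T
        V = solve_triangular(L, Kstar.T, lower=True)
        var = model.sigma_v2 - (V**2).sum(axis=0)
    if include_nugget:
        var = var + model.sigma_e2
    sd = np.sqrt(np.clip(var, 0.0, None))
    if clamp:
        mean = np.clip(mean, 0.0, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# Feed-forward neural network


def _logistic(s):
    return special.expit(s)


@dataclass
class AnnModel:
    """Single-hidden-layer feed-forward network, logistic at every node."""

    W1: np.ndarray  # (hidden, inputs)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    covariate_names: list[str] = field(default_factory=list)
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (1, h) or self.b2.shape != (1,):
            raise ValueError("inconsistent weight shapes")

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.W1.shape[1], self.W1.shape[0], 1)

    def standardize(self, X_raw: np.ndarray) -> np.ndarray:
        X_raw = np.asarray(X_raw, dtype=float)
        if self.col_means is None:
            return X_raw
        return (X_raw - self.col_means) / self.col_sds


def ann_forward(model: AnnModel, x: np.ndarray) -> float:
    """Deterministic forward pass for one input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(f"expected input of length {model.layer_sizes[0]}, got {x.shape}")
    h = _logistic(model.W1 @ x + model.b1)
    return float(_logistic(model.W2 @ h + model.b2)[0])


def _ann_forward_batch(model: AnnModel, X: np.ndarray) -> np.ndarray:
    H = _logistic(X @ model.W1.T + model.b1)
    return _logistic(H @ model.W2.T + model.b2)[:, 0]


def _ann_loss_grad(params, X, y, hidden):
    """Squared-error loss and analytic gradient (flattened parameters)."""
    n, d = X.shape
    W1, b1, W2, b2 = _unpack(params, d, hidden)
    S1 = X @ W1.T + b1
    H = _logistic(S1)
    S2 = H @ W2.T + b2
    out = _logistic(S2)[:, 0]
    err = out - y
    loss = float((err**2).mean())
    # backprop through logistic: f'(s) = f(1-f)
    d_out = (2.0 / n) * err * out * (1 - out)  # (n,)
    gW2 = (d_out @ H)[None, :]
    gb2 = np.array([d_out.sum()])
    dH = d_out[:, None] * W2  # (n, hidden)
    dS1 = dH * H * (1 - H)
    gW1 = dS1.T @ X
    gb1 = dS1.sum(axis=0)
    return loss, _pack(gW1, gb1, gW2, gb2)


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(params, d, hidden):
    i = 0
    W1 = params[i : i + hidden * d].reshape(hidden, d)
    i += hidden * d
    b1 = params[i : i + hidden]
    i += hidden
    W2 = params[i : i + hidden].reshape(1, hidden)
    i += hidden
    b2 = params[i : i + 1]
    return W1, b1, W2, b2


def _train_ann(X, y, hidden, lr, momentum, epochs, rng):
    """Full-batch gradient descent with momentum; returns (params, loss)."""
    d = X.shape[1]
    n_params = hidden * d + hidden + hidden + 1
    params = rng.uniform(-0.5, 0.5, size=n_params)
    velocity = np.zeros(n_params)
    loss = np.inf
    for _ in range(epochs):
        loss, grad = _ann_loss_grad(params, X, y, hidden)
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged")
        velocity = momentum * velocity - lr * grad
        params = params + velocity
    loss, _ = _ann_loss_grad(params, X, y, hidden)
    if not np.isfinite(loss):
        raise FloatingPointError("training diverged")
    return params, loss


@dataclass
class AnnSearchSpace:
    hidden_sizes: tuple[int, ...] = (2, 4, 8, 16)
    learning_rates: tuple[float, ...] = (0.2,)
    momentum: float = 0.9
    epochs: int = 800
    n_repeats: int = 10


def fit_ann(
    design: DesignMatrix,
    y: np.ndarray,
    search_space: AnnSearchSpace | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> AnnModel:
    """Train the network with hyperparameters tuned by repeated random
    70/30 sub-sampling.

    Each (hidden size, learning rate) candidate is scored by mean
    validation MSE over the sub-samples; the winning configuration is then
    trained ``n_restarts`` times on a fixed 70% split and the restart with
    the lowest validation MSE on the held-out 30% is returned.  Diverging
    restarts are logged and skipped; an error is raised only if every
    restart diverges.
    """
    space = search_space or AnnSearchSpace()
    y = np.asarray(y, dtype=float)
    X = design.values
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 rows to train the network")
    if y.size != n:
        raise ValueError("response length mismatch")
    rng = np.random.default_rng(seed)
    n_train = int(round(0.7 * n))
    splits = []
    for _ in range(space.n_repeats):
        perm = rng.permutation(n)
        splits.append((perm[:n_train], perm[n_train:]))

    best_cfg, best_cfg_mse = None, np.inf
    for hidden in space.hidden_sizes:
        for lr in space.learning_rates:
            mses = []
            for train, test in splits:
                try:
                    params, _ = _train_ann(
                        X[train], y[train], hidden, lr, space.momentum, space.epochs, rng
                    )
                except FloatingPointError:
                    logger.warning("divergence at hidden=%d lr=%.3g during tuning", hidden, lr)
                    mses.append(np.inf)
                    continue
                W1, b1, W2, b2 = _unpack(params, X.shape[1], hidden)
                m = AnnModel(W1, b1, W2, b2)
                mses.append(float(((y[test] - _ann_forward_batch(m, X[test])) ** 2).mean()))
            score = float(np.mean(mses))
            if score < best_cfg_mse:
                best_cfg, best_cfg_mse = (hidden, lr), score
    if best_cfg is None:
        raise RuntimeError("all tuning runs diverged")
    hidden, lr = best_cfg

    train, test = splits[0]
    best_params, best_val = None, np.inf
    for _ in range(max(n_restarts, 1)):
        try:
            params, _ = _train_ann(X[train], y[train], hidden, lr, space.momentum, space.epochs, rng)
        except FloatingPointError:
            logger.warning("restart diverged at hidden=%d lr=%.3g", hidden, lr)
            continue
        W1, b1, W2, b2 = _unpack(params, X.shape[1], hidden)
        m = AnnModel(W1, b1, W2, b2)
        val = float(((y[test] - _ann_forward_batch(m, X[test])) ** 2).mean())
        if val < best_val:
            best_params, best_val = params, val
    if best_params is None:
        raise RuntimeError("all restarts diverged")
    W1, b1, W2, b2 = _unpack(best_params, X.shape[1], hidden)
    return AnnModel(
        W1,
        b1,
        W2,
        b2,
        covariate_names=list(design.covariate_names),
        col_means=design.col_means,
        col_sds=design.col_sds,
    )


def fit_ann_ensemble(
    design: DesignMatrix,
    y: np.ndarray,
    n_members: int = 5,
    search_space: AnnSearchSpace | None = None,
    seed: int = 0,
) -> list[AnnModel]:
    """Independently seeded refits used for ANN predictive uncertainty."""
    return [
        fit_ann(design, y, search_space=search_space, n_restarts=1, seed=seed + 1000 * k)
        for k in range(n_members)
    ]


def ann_predict(models: list[AnnModel], X_new: np.ndarray, standardized: bool = True):
    """Ensemble mean and standard deviation across member networks."""
    if not models:
        raise ValueError("empty ensemble")
    X_new = np.asarray(X_new, dtype=float)
    if not standardized:
        X_new = models[0].standardize(X_new)
    preds = np.stack([_ann_forward_batch(m, X_new) for m in models])
    mean = preds.mean(axis=0)
    if len(models) == 1:
        warnings.warn("ensemble of size 1: predictive sd is 0 by convention")
        return mean, np.zeros_like(mean)
    return mean, preds.std(axis=0)


# ---------------------------------------------------------------------------
# Baselines


@dataclass
class MeanModel:
    """Trivial baseline: predicts the training mean everywhere."""

    mean: float

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return np.full(len(X_new), self.mean)


@dataclass
class LinearModel:
    beta: np.ndarray  # intercept first
    covariate_names: list[str] = field(default_factory=list)
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def predict(self, X_new: np.ndarray, standardized: bool = True) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if not standardized and self.col_means is not None:
            X_new = (X_new - self.col_means) / self.col_sds
        return _design_with_intercept(X_new) @ self.beta


def fit_mean_baseline(y: np.ndarray) -> MeanModel:
    return MeanModel(mean=float(np.mean(y)))


def fit_linear(design: DesignMatrix, y: np.ndarray) -> LinearModel:
    """Ordinary least squares on the standardized covariates."""
    reg = LinearRegression().fit(design.values, np.asarray(y, dtype=float))
    beta = np.concatenate([[reg.intercept_], reg.coef_])
    return LinearModel(
        beta=beta,
        covariate_names=list(design.covariate_names),
        col_means=design.col_means,
        col_sds=design.col_sds,
    )
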