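"""Gaussian-process regression over step frequency.

The surrogate for Bayesian optimization: a zero-mean GP with a squared
exponential kernel

    k(x, x') = sigma^2 * exp(-(x - x')^2 / (2 l^2)),

observation noise sigma_n^2 entering only the diagonal of the Gram matrix,
and hyperparameters (sigma^2, l, sigma_n^2) chosen by maximising the log
marginal likelihood with multi-restart bound-constrained local search.

Because metabolic costs are far from zero, the targets are centred by
their sample mean before fitting and the offset is restored in predictions;
the predictive variance reported is that of the latent function value
(without the observation-noise term), which is what expected improvement
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "GPDataset",
    "GPHyperparameters",
    "GPPosterior",
    "kernel",
    "gram_matrix",
    "posterior",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "default_bounds",
]

#: Relative jitter added to the Gram diagonal for factorisation stability.
JITTER_FRAC = 1e-10


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel hyperparameters: signal variance, length scale, noise variance."""

    sigma2: float        # signal variance (cost-units^2)
    length_scale: float  # l (Hz)
    noise2: float        # observation-noise variance sigma_n^2 (cost-units^2)

    def __post_init__(self):
        if not (self.sigma2 > 0 and self.length_scale > 0 and self.noise2 > 0):
            raise ValueError("all hyperparameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2, self.length_scale, self.noise2])


@dataclass
class GPDataset:
    """Evaluated step frequencies X (Hz) and cost estimates y."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_1d(np.asarray(self.X, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.X.shape != self.y.shape:
            raise ValueError("X and y must have equal length")
        if len(self.X) < 1:
            raise ValueError("dataset must contain at least one observation")

    def __len__(self) -> int:
        return len(self.X)

    def append(self, x: float, y: float) -> "GPDataset":
        return GPDataset(np.append(self.X, x), np.append(self.y, y))


def kernel(x: np.ndarray | float, x2: np.ndarray | float,
           hp: GPHyperparameters) -> np.ndarray | float:
    """Squared exponential covariance between step frequencies (off-diagonal
    convention: no noise term)."""
    d = np.subtract(x, x2)
    out = hp.sigma2 * np.exp(-0.5 * (d / hp.length_scale) ** 2)
    return float(out) if np.ndim(out) == 0 else out


def gram_matrix(X: np.ndarray, hp: GPHyperparameters,
                *, jitter: bool = True) -> np.ndarray:
    """Gram matrix K + sigma_n^2 I (noise on the diagonal only)."""
    X = np.asarray(X, dtype=float)
    K = kernel(X[:, None], X[None, :], hp)
    n = len(X)
    diag = hp.noise2
    if jitter:
        diag = diag + JITTER_FRAC * np.trace(K) / n
    return K + diag * np.eye(n)


@dataclass
class GPPosterior:
    """Cached posterior of the cost over step frequency.

    ``mean(x)`` and ``var(x)`` evaluate the predictive mean and the
    latent-function variance at scalar or vector queries.
    """

    data: GPDataset
    hp: GPHyperparameters
    y_offset: float
    _cho: tuple
    _alpha: np.ndarray

    def mean(self, xs: np.ndarray | float) -> np.ndarray | float:
        ks = kernel(np.atleast_1d(np.asarray(xs, float))[:, None],
                    self.data.X[None, :], self.hp)
        m = ks @ self._alpha + self.y_offset
        return float(m[0]) if np.ndim(xs) == 0 else m

    def var(self, xs: np.ndarray | float) -> np.ndarray | float:
        xs_arr = np.atleast_1d(np.asarray(xs, float))
        ks = kernel(xs_arr[:, None], self.data.X[None, :], self.hp)
        v = cho_solve(self._cho, ks.T)
        s2 = self.hp.sigma2 - np.einsum("ij,ji->i", ks, v)
        s2 = np.maximum(s2, 0.0)
        return float(s2[0]) if np.ndim(xs) == 0 else s2

    def sd(self, xs: np.ndarray | float) -> np.ndarray | float:
        return np.sqrt(self.var(xs))


def posterior(data: GPDataset, hp: GPHyperparameters,
              *, center: bool = True) -> GPPosterior:
    """Condition the zero-mean GP on the data.

    Targets are centred by their sample mean (restored in predictions)
    unless ``center=False``.
    """
    offset = float(np.mean(data.y)) if center else 0.0
    yc = data.y - offset
    Ky = gram_matrix(data.X, hp)
    try:
        cho = cho_factor(Ky, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"Gram matrix not positive definite (n={len(data)}, hp={hp})"
        ) from e
    alpha = cho_solve(cho, yc)
    return GPPosterior(data=data, hp=hp, y_offset=offset,
                       _cho=cho, _alpha=alpha)


def log_marginal_likelihood(data: GPDataset, hp: GPHyperparameters,
                            *, center: bool = True,
                            _grad: bool = False):
    """Log marginal likelihood of the (centred) data under the GP prior.

        -1/2 y^T (K+sigma_n^2 I)^-1 y - 1/2 log|K+sigma_n^2 I| - n/2 log 2pi

    With ``_grad=True`` also returns the gradient with respect to
    (log sigma^2, log l, log sigma_n^2).
    """
    offset = float(np.mean(data.y)) if center else 0.0
    yc = data.y - offset
    n = len(data)
    Ky = gram_matrix(data.X, hp)
    cho = cho_factor(Ky, lower=True)
    alpha = cho_solve(cho, yc)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lml = -0.5 * yc @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
    if not _grad:
        return float(lml)
    # dLML/dtheta = 1/2 tr((alpha alpha^T - K^-1) dK/dtheta)
    Kinv = cho_solve(cho, np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    D2 = (np.subtract.outer(data.X, data.X) / hp.length_scale) ** 2
    E = hp.sigma2 * np.exp(-0.5 * D2)       # signal part of K
    g = np.empty(3)
    g[0] = 0.5 * np.sum(W * E)              # d/d log sigma2
    g[1] = 0.5 * np.sum(W * (E * D2))       # d/d log l
    g[2] = 0.5 * hp.noise2 * np.trace(W)    # d/d log noise2
    return float(lml), g


def default_bounds(data: GPDataset, domain: tuple[float, float] | None = None
                   ) -> list[tuple[float, float]]:
    """Hyperparameter bounds scaled to the data.

    Length scale spans [0.02, 2] of the domain width; signal variance
    [1e-4, 1e2] and noise variance [1e-6, 1] of the target variance.
    """
    if domain is None:
        lo, hi = float(np.min(data.X)), float(np.max(data.X))
    else:
        lo, hi = domain
    width = max(hi - lo, 1e-3)
    vy = float(np.var(data.y))
    if vy <= 0:
        vy = max(1e-8, 1e-6 * (1.0 + float(np.mean(data.y)) ** 2))
    return [
        (1e-4 * vy, 1e2 * vy),        # sigma2
        (0.02 * width, 2.0 * width),  # length_scale
        (1e-6 * vy, 1.0 * vy),        # noise2
    ]


def fit_hyperparameters(
    data: GPDataset,
    bounds: list[tuple[float, float]] | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    *,
    domain: tuple[float, float] | None = None,
    center: bool = True,
) -> GPHyperparameters:
    """Maximise the log marginal likelihood over (sigma^2, l, sigma_n^2).

    Bound-constrained L-BFGS-B in log-parameter space with analytic
    gradients, from ``n_restarts`` log-uniform random initialisations
    within the bounds; the restart with the highest likelihood wins.
    Deterministic given the seeded generator.
    """
    if len(data) < 2:
        raise ValueError("hyperparameter fitting needs at least 2 observations")
    rng = np.random.default_rng(rng)
    if bounds is None:
        bounds = default_bounds(data, domain)
    log_bounds = [(np.log(lo), np.log(hi)) for lo, hi in bounds]

    def neg_lml(z):
        hp = GPHyperparameters(*np.exp(z))
        try:
            lml, g = log_marginal_likelihood(data, hp, center=center, _grad=True)
        except np.linalg.LinAlgError:
            return 1e25, np.zeros(3)
        return -lml, -g

    starts = [np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
              for _ in range(n_restarts)]
    best, best_val, last_err = None, np.inf, None
    for z0 in starts:
        try:
            res = minimize(neg_lml, z0, jac=True, method="L-BFGS-B",
                           bounds=log_bounds)
        except Exception as e:  # pragma: no cover - solver failure path
            last_err = e
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best = res.fun, res.x
    if best is None:
        raise RuntimeError(f"all hyperparameter restarts failed: {last_err}")
    return GPHyperparameters(*np.exp(best))
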