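"""Asymmetric Laplace distribution (ALD) primitives and check-loss regression.

The ALD with location ``mu``, scale ``sigma`` and skewness ``tau`` has density

    f(y) = tau * (1 - tau) / sigma * exp(-rho_tau((y - mu) / sigma)),

where ``rho_tau(u) = u * (tau - 1{u < 0})`` is the quantile check loss.  Its
tau-th quantile is exactly ``mu``, which is what makes ALD maximum likelihood
equivalent to check-loss minimization and hence to quantile regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import linprog

SIGMA_FLOOR = 1e-10


def _validate_tau(tau: float) -> None:
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie in the open interval (0, 1); got {tau!r}")


@dataclass(frozen=True)
class ALDParams:
    """Location mu, scale sigma > 0 and quantile level tau in (0, 1)."""

    mu: float = 0.0
    sigma: float = 1.0
    tau: float = 0.5

    def __post_init__(self) -> None:
        _validate_tau(self.tau)
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive; got {self.sigma!r}")


@dataclass
class CheckRegressionProblem:
    """A weighted linear quantile-regression problem.

    Minimize sum_i w_i * rho_tau(y_i - x_i' beta) over beta.
    """

    design: NDArray[np.float64]
    response: NDArray[np.float64]
    weights: NDArray[np.float64]
    tau: float

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        _validate_tau(self.tau)
        n, p = self.design.shape
        if len(self.response) != n or len(self.weights) != n:
            raise ValueError("design rows, response and weights must have equal length")
        if p < 1:
            raise ValueError("design must have at least one column")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("empty problem: all weights are zero")


def check_loss(u: ArrayLike, tau: float) -> NDArray[np.float64] | float:
    """Quantile check loss rho_tau(u) = u * (tau - 1{u < 0}).

    Nonnegative, convex, piecewise linear; zero only at u = 0.
    """
    _validate_tau(tau)
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


def ald_logpdf(y: ArrayLike, p: ALDParams) -> NDArray[np.float64] | float:
    """Log-density of the ALD; maximal at y = mu with value log(tau(1-tau)/sigma)."""
    sigma = max(p.sigma, SIGMA_FLOOR)
    y = np.asarray(y, dtype=float)
    out = np.log(p.tau * (1.0 - p.tau)) - np.log(sigma) - check_loss((y - p.mu) / sigma, p.tau)
    return float(out) if out.ndim == 0 else out


def ald_cdf(y: ArrayLike, p: ALDParams) -> NDArray[np.float64] | float:
    """ALD distribution function; F(mu) = tau (the zero-quantile constraint)."""
    sigma = max(p.sigma, SIGMA_FLOOR)
    y = np.asarray(y, dtype=float)
    z = (y - p.mu) / sigma
    lower = p.tau * np.exp((1.0 - p.tau) * np.minimum(z, 0.0))
    upper = 1.0 - (1.0 - p.tau) * np.exp(-p.tau * np.maximum(z, 0.0))
    out = np.where(z <= 0.0, lower, upper)
    return float(out) if out.ndim == 0 else out


def ald_quantile(prob: ArrayLike, p: ALDParams) -> NDArray[np.float64] | float:
    """Inverse of :func:`ald_cdf`; returns mu at prob = tau."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob <= 0.0) or np.any(prob >= 1.0):
        raise ValueError("prob must lie in the open interval (0, 1)")
    sigma = max(p.sigma, SIGMA_FLOOR)
    with np.errstate(divide="ignore"):
        low = p.mu + sigma / (1.0 - p.tau) * np.log(np.minimum(prob, p.tau) / p.tau)
        high = p.mu - sigma / p.tau * np.log((1.0 - np.maximum(prob, p.tau)) / (1.0 - p.tau))
    out = np.where(prob <= p.tau, low, high)
    return float(out) if out.ndim == 0 else out


def ald_sample(
    n: int, p: ALDParams, seed: int | np.random.Generator | None = None
) -> NDArray[np.float64]:
    """Draw ``n`` i.i.d. ALD variates by the inverse-CDF transform."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # keep u strictly inside (0, 1) so the inverse transform is finite
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return np.asarray(ald_quantile(u, p), dtype=float)


def check_objective(
    beta: ArrayLike,
    design: NDArray[np.float64],
    response: NDArray[np.float64],
    weights: NDArray[np.float64],
    tau: float,
) -> float:
    """Weighted check-loss objective sum_i w_i rho_tau(y_i - x_i' beta)."""
    resid = response - design @ np.asarray(beta, dtype=float)
    return float(np.sum(weights * check_loss(resid, tau)))


def _solve_lp(X, y, w, tau):
    n, p = X.shape
    # variables: beta (free, p), u+ (n), u- (n); residual y - X beta = u+ - u-
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w])
    a_eq_beta = X
    from scipy.sparse import eye, hstack, csr_matrix

    a_eq = hstack([csr_matrix(a_eq_beta), eye(n, format="csr"), -eye(n, format="csr")])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise np.linalg.LinAlgError(f"quantile-regression LP failed: {res.message}")
    return res.x[:p]


def _solve_irls(X, y, w, tau, max_iter=100, eps_schedule=(1e-6, 1e-9, 1e-12), tol=1e-13):
    # Iteratively reweighted least squares for the check loss: each residual
    # contributes rho_tau(r) ~= c(r) * r^2 with c = w * (tau or 1-tau) / |r|.
    # The smoothing floor eps is annealed toward zero, warm-starting each
    # stage, which brings the objective within ~1e-11 (relative) of the LP.
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X * w[:, None] ** 0.5, y * w**0.5, rcond=None)
    best_beta, best_obj = beta, check_objective(beta, X, y, w, tau)
    for eps in eps_schedule:
        prev_obj = np.inf
        for _ in range(max_iter):
            r = y - X @ beta
            asym = np.where(r >= 0, tau, 1.0 - tau)
            c = w * asym / np.maximum(np.abs(r), eps)
            wx = X * c[:, None]
            beta = np.linalg.solve(X.T @ wx + 1e-12 * np.eye(p), wx.T @ y)
            obj = check_objective(beta, X, y, w, tau)
            if obj < best_obj:
                best_beta, best_obj = beta, obj
            if abs(prev_obj - obj) <= tol * (1.0 + abs(obj)):
                break
            prev_obj = obj
    return best_beta


def weighted_check_regression(
    prob: CheckRegressionProblem, method: str = "lp"
) -> NDArray[np.float64]:
    """Minimize the weighted check loss over coefficients.

    ``method='lp'`` solves the exact linear program (residuals split into
    positive/negative slacks, HiGHS solver).  ``method='irls'`` is an
    iteratively reweighted least-squares path for large stacked problems; the
    two agree in objective value.  Quantile-regression solutions can be
    non-unique on small problems, so downstream comparisons are made on the
    objective, not on coefficient identity.
    """
    keep = prob.weights > 0
    X = prob.design[keep]
    y = prob.response[keep]
    w = prob.weights[keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design is rank-deficient on rows with positive weight"
        )
    if method == "lp":
        return _solve_lp(X, y, w, prob.tau)
    if method == "irls":
        return _solve_irls(X, y, w, prob.tau)
    raise ValueError(f"unknown method {method!r}")
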