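"""SAEM estimation of quantile linear mixed-effects models.

Model: y_ij = x_ij' beta_tau + z_ij' b_i + eps_ij, with b_i ~ N_r(0, Psi) and
eps_ij ~ ALD(0, sigma, tau).  The random effects are the missing data; each
SAEM iteration simulates them per subject by random-walk Metropolis-Hastings,
smooths the complete-data statistics with the stochastic-approximation weights

    delta_k = 1            for 1 <= k <= c*W,
    delta_k = 1/(k - c*W)  for c*W < k <= W,

and maximizes the smoothed objective.  The check loss has no finite-dimensional
sufficient statistic, so the Q-function for (beta, sigma) is carried through a
weighted pool of retained draws; the Gaussian part (Psi) is smoothed through
per-subject second moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.linalg import cho_factor, cho_solve

from .ald import CheckRegressionProblem, check_loss, weighted_check_regression
from .data import DesignBundle, LongitudinalDataset, ModelSpec, build_designs

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-8
PSI_EIG_FLOOR = 1e-8


@dataclass
class ThetaState:
    """Parameter state: fixed effects, ALD scale and random-effects dispersion."""

    beta: NDArray[np.float64]
    sigma: float
    psi: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.psi.size and not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")

    @property
    def r(self) -> int:
        return self.psi.shape[0] if self.psi.size else 0

    @property
    def alpha(self) -> NDArray[np.float64]:
        """Distinct (lower-triangular) elements of Psi."""
        idx = np.tril_indices(self.r)
        return self.psi[idx]

    @property
    def cholesky(self) -> NDArray[np.float64]:
        return np.linalg.cholesky(self.psi)

    def flat(self) -> NDArray[np.float64]:
        return np.concatenate([self.beta, [self.sigma], self.alpha])


@dataclass
class SAEMConfig:
    """Tuning knobs for the SAEM loop.

    ``W`` is the iteration cap, ``c`` the fraction of memory-free iterations,
    ``m`` the retained draws per subject per iteration (values above 20 are
    rarely useful and trigger a warning).
    """

    W: int = 500
    c: float = 0.25
    m: int = 20
    mh_proposal_scale: float = 1.4
    burn_in_per_iteration: int = 10
    pool_weight_floor: float = 1e-4
    convergence_tol: float = 1e-4
    convergence_window: int = 10
    seed: int = 0
    tune_proposal: bool = True
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if self.W < 2:
            raise ValueError("W must be at least 2")
        if not (0.0 < self.c < 1.0):
            raise ValueError("c must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.m > 20:
            logger.warning("m=%d exceeds the recommended ceiling of 20", self.m)
        if self.convergence_tol <= 0 or self.pool_weight_floor <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class RandomEffectsDraws:
    """Per-subject retained MH draws and acceptance rates for one iteration."""

    draws: NDArray[np.float64]  # (n_subjects, m, r)
    acceptance_rate: NDArray[np.float64]  # (n_subjects,)


@dataclass
class PoolEntry:
    draws: NDArray[np.float64]  # (n_subjects, m_e, r)
    weight: float  # per-draw weight
    pseudo: NDArray[np.float64] | None = None  # cached y - Z b, (N_obs, m_e)


@dataclass
class SAState:
    """Stochastic-approximation accumulators across iterations."""

    pool: list = field(default_factory=list)  # list[PoolEntry]
    S2: NDArray[np.float64] | None = None  # (n, r, r) smoothed second moments
    mean_check: float = 0.0
    k: int = 0

    def total_draw_weight(self) -> float:
        return sum(e.weight * e.draws.shape[1] for e in self.pool)

    def update_pool(
        self, draws: NDArray, delta: float, floor: float, pseudo: NDArray | None = None
    ) -> None:
        for e in self.pool:
            e.weight *= 1.0 - delta
        m = draws.shape[1]
        self.pool.append(PoolEntry(draws=draws, weight=delta / m, pseudo=pseudo))
        self.pool = [e for e in self.pool if e.weight >= floor]


def delta_schedule(k: int, c: float, W: int) -> float:
    """Stochastic-approximation step size: 1 in the memory-free phase
    (k <= c*W), then 1/(k - c*W)."""
    if not 1 <= k <= W:
        raise ValueError(f"iteration k={k} outside [1, W={W}]")
    cut = int(np.floor(c * W))
    if k <= cut:
        return 1.0
    return 1.0 / (k - cut)


def sa_update(prev, batch, delta: float):
    """One stochastic-approximation step: prev + delta * (batch - prev)."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    prev = np.asarray(prev, dtype=float)
    batch = np.asarray(batch, dtype=float)
    if prev.shape != batch.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {batch.shape}")
    out = prev + delta * (batch - prev)
    return float(out) if out.ndim == 0 else out


def mvn_logpdf(b: NDArray, psi: NDArray) -> float:
    """N_r(0, Psi) log-density."""
    b = np.asarray(b, dtype=float).ravel()
    r = len(b)
    if r == 0:
        return 0.0
    try:
        cf = cho_factor(psi, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("psi is not positive definite") from exc
    quad = b @ cho_solve(cf, b)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (r * np.log(2.0 * np.pi) + logdet + quad))


def complete_loglik(
    theta: ThetaState,
    X: NDArray,
    Z: NDArray,
    y: NDArray,
    b: NDArray,
    tau: float,
) -> float:
    """Complete-data log-likelihood of one subject: ALD terms plus the
    Gaussian random-effects prior."""
    sigma = max(theta.sigma, SIGMA_FLOOR)
    y = np.asarray(y, dtype=float).ravel()
    n_i = len(y)
    ll = 0.0
    if n_i:
        resid = y - X @ theta.beta - (Z @ b if Z.shape[1] else 0.0)
        ll += n_i * (np.log(tau * (1.0 - tau)) - np.log(sigma))
        ll -= float(np.sum(check_loss(resid / sigma, tau)))
    ll += mvn_logpdf(b, theta.psi)
    return ll


# ---------------------------------------------------------------------------
# padded per-subject structures for vectorized MH across subjects
# ---------------------------------------------------------------------------


class _Padded:
    def __init__(self, designs: DesignBundle):
        n = designs.n
        J = max(len(yi) for yi in designs.y)
        p, r = designs.p, designs.r
        self.X = np.zeros((n, J, p))
        self.Z = np.zeros((n, J, r))
        self.y = np.zeros((n, J))
        self.mask = np.zeros((n, J), dtype=bool)
        for i in range(n):
            ni = len(designs.y[i])
            self.X[i, :ni] = designs.X[i]
            self.Z[i, :ni] = designs.Z[i]
            self.y[i, :ni] = designs.y[i]
            self.mask[i, :ni] = True
        self.n, self.J, self.p, self.r = n, J, p, r
        # row-stacked views for the M-step
        self.X_stack = np.vstack(designs.X)
        self.Z_stack = np.vstack(designs.Z)
        self.y_stack = np.concatenate(designs.y)
        self.subj_idx = np.repeat(np.arange(n), [len(yi) for yi in designs.y])


def _log_target(pad: _Padded, b: NDArray, beta: NDArray, sigma: float,
                psi_inv: NDArray, tau: float) -> NDArray:
    """Per-subject unnormalized log posterior of the random effects."""
    mean = pad.X @ beta + np.einsum("njr,nr->nj", pad.Z, b)
    resid = (pad.y - mean) / sigma
    cl = np.where(pad.mask, resid * (tau - (resid < 0)), 0.0).sum(axis=1)
    quad = 0.5 * np.einsum("nr,rs,ns->n", b, psi_inv, b)
    return -cl - quad


def mh_sample_subjects(
    pad: _Padded,
    theta: ThetaState,
    tau: float,
    m: int,
    burn_in: int,
    scale: NDArray,
    start: NDArray,
    rng: np.random.Generator,
) -> RandomEffectsDraws:
    """Random-walk Metropolis for all subjects in parallel.

    Proposal: b' = b + scale_i * L eps with L the Cholesky factor of the
    current Psi; ``burn_in`` discarded steps, then ``m`` retained.
    """
    n, r = start.shape
    L = theta.cholesky
    psi_inv = np.linalg.inv(theta.psi)
    sigma = max(theta.sigma, SIGMA_FLOOR)
    b = start.copy()
    lp = _log_target(pad, b, theta.beta, sigma, psi_inv, tau)
    draws = np.empty((n, m, r))
    accepted = np.zeros(n)
    total = burn_in + m
    for step in range(total):
        eps = rng.standard_normal((n, r))
        prop = b + scale[:, None] * (eps @ L.T)
        lp_prop = _log_target(pad, prop, theta.beta, sigma, psi_inv, tau)
        accept = np.log(rng.uniform(size=n)) < (lp_prop - lp)
        b[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        accepted += accept
        if step >= burn_in:
            draws[:, step - burn_in, :] = b
    rate = accepted / total
    if np.any(rate == 0.0):
        logger.debug("MH rejected every proposal for %d subject(s)", int((rate == 0).sum()))
    return RandomEffectsDraws(draws=draws, acceptance_rate=rate)


def mh_sample_subject(
    X: NDArray,
    Z: NDArray,
    y: NDArray,
    theta: ThetaState,
    tau: float,
    m: int,
    burn_in: int = 10,
    scale: float = 1.4,
    start: NDArray | None = None,
    rng: np.random.Generator | None = None,
) -> RandomEffectsDraws:
    """Single-subject convenience wrapper around :func:`mh_sample_subjects`."""
    rng = rng or np.random.default_rng()
    r = theta.r
    bundle = DesignBundle(
        subjects=[0],
        X=[np.atleast_2d(X)],
        Z=[np.atleast_2d(Z) if np.size(Z) else np.empty((len(np.atleast_1d(y)), r))],
        y=[np.atleast_1d(y)],
        fixed_terms=tuple(f"x{i}" for i in range(np.atleast_2d(X).shape[1])),
        random_terms=tuple(f"z{i}" for i in range(r)),
    )
    pad = _Padded(bundle)
    start_arr = np.zeros((1, r)) if start is None else np.atleast_2d(start)
    return mh_sample_subjects(pad, theta, tau, m, burn_in, np.array([scale]), start_arr, rng)


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------


def _pool_pseudo_responses(pad: _Padded, sa: SAState):
    """Stack pool entries into a pseudo-response matrix.

    Returns (Y (N, D), colw (D,)): column l of Y is y - Z b for one retained
    draw; colw carries the pool weight of that draw.  All columns share the
    same fixed-effects design rows, which keeps the weighted check regression
    cheap.
    """
    y_cols, w_cols = [], []
    for e in sa.pool:
        if e.pseudo is None:
            e.pseudo = _pseudo_responses(pad, e.draws)
        y_cols.append(e.pseudo)
        w_cols.append(np.full(e.draws.shape[1], e.weight))
    return np.concatenate(y_cols, axis=1), np.concatenate(w_cols)


def _pseudo_responses(pad: _Padded, draws: NDArray) -> NDArray:
    B_rows = draws[pad.subj_idx]  # (N, m_e, r)
    zb = np.einsum("nr,nmr->nm", pad.Z_stack, B_rows) if pad.r else 0.0
    return pad.y_stack[:, None] - zb


def _matrix_irls_qr(X, Y, colw, tau, beta0, max_iter=50, eps=1e-8, tol=1e-11):
    """Weighted check-loss minimization over columns sharing design X."""
    p = X.shape[1]
    beta = beta0.copy()
    prev = np.inf
    for _ in range(max_iter):
        R = Y - (X @ beta)[:, None]
        asym = np.where(R >= 0, tau, 1.0 - tau)
        C = colw[None, :] * asym / np.maximum(np.abs(R), eps)
        crs = C.sum(axis=1)
        A = X.T @ (X * crs[:, None]) + 1e-12 * np.eye(p)
        bv = X.T @ (C * Y).sum(axis=1)
        beta = np.linalg.solve(A, bv)
        obj = float(np.sum(colw[None, :] * check_loss(Y - (X @ beta)[:, None], tau)))
        if abs(prev - obj) <= tol * (1.0 + abs(obj)):
            break
        prev = obj
    return beta


def mstep_beta(
    pad: _Padded,
    sa: SAState,
    tau: float,
    beta0: NDArray,
    lp_row_limit: int = 4000,
) -> NDArray:
    """Minimize the pool-weighted check loss in beta.

    Small stacked problems go through the exact LP of
    :func:`qlmm.ald.weighted_check_regression`; larger ones through an IRLS
    path that exploits the shared design across pool columns (same minimizer,
    verified on the objective).
    """
    if not sa.pool:
        raise ValueError("draw pool is empty")
    Y, colw = _pool_pseudo_responses(pad, sa)
    N, D = Y.shape
    if N * D <= lp_row_limit:
        design = np.tile(pad.X_stack, (D, 1))
        resp = Y.T.ravel()
        wts = np.repeat(colw, N)
        prob = CheckRegressionProblem(design=design, response=resp, weights=wts, tau=tau)
        return weighted_check_regression(prob, method="lp")
    return _matrix_irls_qr(pad.X_stack, Y, colw, tau, beta0)


def pool_objective(pad: _Padded, sa: SAState, beta: NDArray, tau: float) -> float:
    """Pool-weighted mean per-observation check loss at beta."""
    Y, colw = _pool_pseudo_responses(pad, sa)
    R = Y - (pad.X_stack @ beta)[:, None]
    total_w = colw.sum() * Y.shape[0]
    return float(np.sum(colw[None, :] * check_loss(R, tau)) / max(total_w, 1e-300))


def mstep_sigma(residuals, tau: float, weights=None, floor: float = SIGMA_FLOOR) -> float:
    """Closed-form ALD scale update: the weighted mean check loss of the
    residuals (the stationary point of the ALD likelihood in sigma)."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if weights is None:
        weights = np.ones_like(residuals)
    weights = np.asarray(weights, dtype=float).ravel()
    tw = weights.sum()
    if tw <= 0:
        raise ValueError("total weight must be positive")
    sigma = float(np.sum(weights * check_loss(residuals, tau)) / tw)
    return max(sigma, floor)


def _pool_sigma(pad: _Padded, sa: SAState, beta: NDArray, tau: float) -> float:
    return max(pool_objective(pad, sa, beta, tau), SIGMA_FLOOR)


def mstep_psi(S2: NDArray, eig_floor: float = PSI_EIG_FLOOR) -> NDArray:
    """Average the smoothed per-subject second moments and project to SPD."""
    S2 = np.asarray(S2, dtype=float)
    psi = S2.mean(axis=0)
    psi = 0.5 * (psi + psi.T)
    w, V = np.linalg.eigh(psi)
    if np.any(w < eig_floor):
        psi = (V * np.maximum(w, eig_floor)) @ V.T
        psi = 0.5 * (psi + psi.T)
    return psi


def initialize_params(
    designs: DesignBundle, tau: float, psi_init: str = "moment", psi_scale: float = 0.1
) -> ThetaState:
    """Start values for the SAEM loop.

    beta0 is the fixed-effects-only quantile regression; sigma0 its mean
    check loss.  ``psi_init='moment'`` seeds Psi with the covariance of
    per-subject least-squares projections of the initial residuals onto Z_i
    (EM moves variance components slowly, so starting near a moment estimate
    matters); ``psi_init='identity'`` uses 0.1 * I.
    """
    X, y = designs.stacked()
    prob = CheckRegressionProblem(design=X, response=y, weights=np.ones(len(y)), tau=tau)
    beta0 = weighted_check_regression(prob, method="lp")
    resid = y - X @ beta0
    sigma0 = max(float(np.mean(check_loss(resid, tau))), SIGMA_FLOOR)
    r = designs.r
    psi0 = psi_scale * np.eye(r)
    if psi_init == "moment" and r:
        b_hats = []
        offset = 0
        for Xi, Zi, yi in zip(designs.X, designs.Z, designs.y):
            ni = len(yi)
            ri = resid[offset:offset + ni]
            offset += ni
            if ni > r and np.linalg.matrix_rank(Zi) == r:
                b_hats.append(np.linalg.lstsq(Zi, ri, rcond=None)[0])
        if len(b_hats) > r:
            b_hats = np.asarray(b_hats)
            cand = b_hats.T @ b_hats / len(b_hats)
            w, V = np.linalg.eigh(0.5 * (cand + cand.T))
            psi0 = (V * np.maximum(w, PSI_EIG_FLOOR)) @ V.T
    return ThetaState(beta=beta0, sigma=sigma0, psi=psi0)


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------


def _fit_fixed_only(designs: DesignBundle, tau: float, cfg: SAEMConfig,
                    compute_se: bool = True):
    from .inference import FitResult, louis_se  # local import to avoid a cycle

    X, y = designs.stacked()
    prob = CheckRegressionProblem(design=X, response=y, weights=np.ones(len(y)), tau=tau)
    beta = weighted_check_regression(prob, method="lp")
    resid = y - X @ beta
    sigma = max(float(np.mean(check_loss(resid, tau))), SIGMA_FLOOR)
    n_total = len(y)
    loglik = float(
        n_total * (np.log(tau * (1.0 - tau)) - np.log(sigma))
        - np.sum(check_loss(resid / sigma, tau))
    )
    theta = ThetaState(beta=beta, sigma=sigma, psi=np.empty((0, 0)))
    se = None
    if compute_se:
        pad = _Padded(designs)
        sa = SAState()
        sa.update_pool(np.zeros((designs.n, 1, 0)), 1.0, 0.0,
                       pseudo=pad.y_stack[:, None])
        se = louis_se(pad, sa, theta, tau)
    traces = pd.DataFrame(
        [{"iteration": 0, "delta": np.nan, "sigma": sigma, "objective": sigma,
          **{f"beta_{j}": bj for j, bj in enumerate(beta)}}]
    )
    return FitResult(
        theta=theta,
        tau=tau,
        loglik=loglik,
        N=n_total,
        n_subjects=designs.n,
        fixed_terms=designs.fixed_terms,
        random_terms=designs.random_terms,
        converged=True,
        seed=cfg.seed,
        traces=traces,
        subject_effects=np.zeros((designs.n, 0)),
        acceptance_rate=np.nan,
        se=se,
    )


def fit_qrlmm(
    ds: LongitudinalDataset,
    spec: ModelSpec,
    cfg: SAEMConfig | None = None,
    compute_loglik: bool = True,
    compute_se: bool = True,
    loglik_draws: int = 500,
):
    """Fit the quantile linear mixed model at ``spec.tau`` by SAEM.

    With no random terms the problem is a plain quantile regression and is
    solved directly by LP.  Otherwise the E/SA/M loop runs for at most
    ``cfg.W`` iterations, stopping early when every parameter's relative
    change stays below ``cfg.convergence_tol`` for ``cfg.convergence_window``
    consecutive iterations.  Same seed, same result.
    """
    from .inference import FitResult, marginal_loglik_from_designs, louis_se

    cfg = cfg or SAEMConfig()
    designs = build_designs(ds, spec)
    tau = spec.tau
    if not (0.05 <= tau <= 0.95):
        logger.warning("tau=%.3f is outside [0.05, 0.95]; estimates may be unstable", tau)
    if not (0.01 <= tau <= 0.99):
        raise ValueError("tau must lie in [0.01, 0.99]")

    if designs.r == 0:
        return _fit_fixed_only(designs, tau, cfg, compute_se=compute_se)

    rng = np.random.default_rng(cfg.seed)
    pad = _Padded(designs)
    n, r = pad.n, pad.r
    theta = initialize_params(designs, tau)
    sa = SAState(S2=np.tile((0.1 * np.eye(r))[None], (n, 1, 1)))
    b_current = np.zeros((n, r))
    scale = np.full(n, cfg.mh_proposal_scale)
    cut = int(np.floor(cfg.c * cfg.W))

    rows = []
    flat_prev = theta.flat()
    stable = 0
    converged = False
    obj_prev = np.inf

    for k in range(1, cfg.W + 1):
        delta = delta_schedule(k, cfg.c, cfg.W)
        re = mh_sample_subjects(
            pad, theta, tau, cfg.m, cfg.burn_in_per_iteration, scale, b_current, rng
        )
        b_current = re.draws[:, -1, :].copy()  # warm start next iteration
        if cfg.tune_proposal and k <= cut:
            scale = np.clip(
                scale * np.exp(re.acceptance_rate - cfg.target_acceptance), 1e-3, 50.0
            )

        sa.update_pool(
            re.draws, delta, cfg.pool_weight_floor,
            pseudo=_pseudo_responses(pad, re.draws),
        )
        batch_S2 = np.einsum("nmr,nms->nrs", re.draws, re.draws) / cfg.m
        sa.S2 = sa_update(sa.S2, batch_S2, delta)
        sa.k = k

        Y, colw = _pool_pseudo_responses(pad, sa)
        norm = colw.sum() * Y.shape[0]

        def _obj(b):
            R = Y - (pad.X_stack @ b)[:, None]
            return float(np.sum(colw[None, :] * check_loss(R, tau)) / norm)

        obj_before = _obj(theta.beta)
        beta = _matrix_irls_qr(pad.X_stack, Y, colw, tau, theta.beta)
        obj_after = _obj(beta)
        if obj_after > obj_before + 1e-9 * (1.0 + abs(obj_before)):
            # IRLS did not improve on the warm start; keep the previous beta
            beta, obj_after = theta.beta, obj_before
        sigma = max(obj_after, SIGMA_FLOOR)
        psi = mstep_psi(sa.S2)
        theta = ThetaState(beta=beta, sigma=sigma, psi=psi)

        flat = theta.flat()
        denom = np.maximum(np.abs(flat_prev), 1e-3)
        rel_change = float(np.max(np.abs(flat - flat_prev) / denom))
        flat_prev = flat
        rows.append(
            {
                "iteration": k,
                "delta": delta,
                "sigma": sigma,
                "objective": obj_after,
                "objective_pre_mstep": obj_before,
                "acceptance_mean": float(re.acceptance_rate.mean()),
                "rel_change": rel_change,
                **{f"beta_{j}": bj for j, bj in enumerate(beta)},
                **{
                    f"psi_{a}{b2}": psi[a, b2]
                    for a in range(r)
                    for b2 in range(a + 1)
                },
            }
        )
        if k % 10 == 0:
            logger.info("SAEM iter %d: delta=%.4g sigma=%.4g rel_change=%.3g", k, delta, sigma, rel_change)
        obj_prev = obj_after
        if k > cut:
            stable = stable + 1 if rel_change < cfg.convergence_tol else 0
            if stable >= cfg.convergence_window:
                converged = True
                break

    if not converged:
        logger.info("SAEM reached W=%d without meeting the numeric criterion", cfg.W)

    # pool-weighted posterior means of the random effects
    tw = sa.total_draw_weight()
    b_hat = sum(e.weight * e.draws.sum(axis=1) for e in sa.pool) / max(tw, 1e-300)

    loglik = np.nan
    if compute_loglik:
        # importance-sampling proposal: smoothed posterior covariance,
        # inflated for heavier tails than the target
        b_cov = 1.5 * (sa.S2 - np.einsum("nr,ns->nrs", b_hat, b_hat))
        loglik = marginal_loglik_from_designs(
            designs, theta, tau, b_hat=b_hat, b_cov=b_cov, M=loglik_draws,
            seed=int(rng.integers(2**31 - 1)),
        )
    se = None
    if compute_se:
        se = louis_se(pad, sa, theta, tau)

    return FitResult(
        theta=theta,
        tau=tau,
        loglik=float(loglik),
        N=designs.N,
        n_subjects=designs.n,
        fixed_terms=designs.fixed_terms,
        random_terms=designs.random_terms,
        converged=converged,
        seed=cfg.seed,
        traces=pd.DataFrame(rows),
        subject_effects=b_hat,
        acceptance_rate=float(np.mean([row["acceptance_mean"] for row in rows])),
        se=se,
        _pad=pad,
        _sa=sa,
    )
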