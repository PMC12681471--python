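"""Hierarchical ordered probit: likelihood, analytic score, and fitting.

The latent health index is ``h* = x'beta + eps`` with standard-normal
``eps`` (the scale normalization) and no intercept (absorbed into the
first cut-point). Cut-points follow the exponential-increment scheme

    tau_1 = lambda_1 + gamma_1' z
    tau_j = tau_{j-1} + exp(lambda_j + gamma_j' z),   j = 2..4

which keeps tau_1 < tau_2 < tau_3 < tau_4 for every parameter value, so
covariates can shift reporting thresholds without ever crossing them.
The observed level is j when tau_{j-1} <= h* < tau_j (tau_0 = -inf,
tau_5 = +inf). Estimation maximizes the survey-weighted log-likelihood

    lnL = sum_i w_i ln[ Phi(tau_{i,j(i)} - x_i'beta)
                        - Phi(tau_{i,j(i)-1} - x_i'beta) ].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from .designs import LatentDesign, ThresholdDesign, _check_disjoint

logger = logging.getLogger(__name__)

__all__ = ["HopitParams", "FittedHopit", "latent_index", "thresholds",
           "log_likelihood", "score", "fit"]

N_LEVELS = 5
N_CUTS = N_LEVELS - 1

#: probability floor before taking logs; prevents -inf at extreme arguments
_PROB_FLOOR = 1e-300
#: cap on the exponent of a threshold increment; beyond this the increment
#: would overflow well before the likelihood is informative
_EXP_CLIP = 30.0


@dataclass(frozen=True)
class HopitParams:
    """Model parameters: latent slopes, cut-point intercepts and slopes.

    ``beta`` has one entry per latent-design column; ``lam`` holds the four
    cut-point intercepts; ``gamma`` is a (4, q) array with row j-1 holding
    the cut-point-j slopes over the threshold-design columns.
    """

    beta: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "gamma", gamma)
        if lam.shape != (N_CUTS,):
            raise ValueError(f"lam must have shape ({N_CUTS},)")
        if gamma.ndim != 2 or gamma.shape[0] != N_CUTS:
            raise ValueError(f"gamma must have shape ({N_CUTS}, q)")
        for arr, name in ((beta, "beta"), (lam, "lam"), (gamma, "gamma")):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_free(self) -> int:
        return self.beta.size + N_CUTS + self.gamma.size

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.lam, self.gamma.ravel()])

    @classmethod
    def unpack(cls, theta: np.ndarray, p: int, q: int) -> "HopitParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size != p + N_CUTS + N_CUTS * q:
            raise ValueError("parameter vector has wrong length")
        return cls(
            beta=theta[:p],
            lam=theta[p : p + N_CUTS],
            gamma=theta[p + N_CUTS :].reshape(N_CUTS, q),
        )

    def parameter_names(
        self, latent: LatentDesign, threshold: ThresholdDesign
    ) -> list[str]:
        names = [f"beta:{c}" for c in latent.column_names]
        names += [f"lambda:{j}" for j in range(1, N_CUTS + 1)]
        for j in range(1, N_CUTS + 1):
            names += [f"gamma{j}:{c}" for c in threshold.column_names]
        return names


def latent_index(params: HopitParams, latent: LatentDesign) -> np.ndarray:
    """Deterministic part of the latent health index, ``x'beta`` per row."""
    X = latent.matrix
    if X.shape[1] != params.beta.size:
        raise ValueError(
            f"beta has {params.beta.size} entries but latent design has "
            f"{X.shape[1]} columns"
        )
    return X @ params.beta


def _eta(params: HopitParams, threshold: ThresholdDesign) -> np.ndarray:
    """Linear predictors lambda_j + gamma_j'z, shape (n, 4)."""
    Z = threshold.matrix
    if Z.shape[1] != params.gamma.shape[1]:
        raise ValueError(
            f"gamma has {params.gamma.shape[1]} columns but threshold design "
            f"has {Z.shape[1]}"
        )
    return params.lam[None, :] + Z @ params.gamma.T


def thresholds(params: HopitParams, threshold: ThresholdDesign) -> np.ndarray:
    """Per-row cut-points (tau_1..tau_4), shape (n, 4), strictly increasing.

    The implicit outer cut-points tau_0 = -inf and tau_5 = +inf are not
    stored.
    """
    eta = _eta(params, threshold)
    clipped = np.clip(eta[:, 1:], -_EXP_CLIP, _EXP_CLIP)
    if (clipped != eta[:, 1:]).any():
        logger.warning("threshold increment exponents clipped at ±%g", _EXP_CLIP)
    tau = np.empty_like(eta)
    tau[:, 0] = eta[:, 0]
    tau[:, 1:] = np.exp(clipped)
    return np.cumsum(tau, axis=1)


def _interval_bounds(
    tau: np.ndarray, xb: np.ndarray, outcome: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized upper/lower interval bounds (a, b) per row."""
    n = tau.shape[0]
    padded = np.column_stack(
        [np.full(n, -np.inf), tau, np.full(n, np.inf)]
    )  # tau_0..tau_5
    rows = np.arange(n)
    upper = padded[rows, outcome]          # tau_j
    lower = padded[rows, outcome - 1]      # tau_{j-1}
    return upper - xb, lower - xb


def _interval_prob(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Phi(a) - Phi(b) evaluated in the numerically favourable tail.

    For intervals far in the right tail, Phi(a) and Phi(b) both round to 1;
    the survivor-function form Phi(-b) - Phi(-a) keeps precision there.
    """
    direct = ndtr(a) - ndtr(b)
    flipped = ndtr(-b) - ndtr(-a)
    mid_positive = np.where(np.isfinite(a), a, 0.0) + np.where(
        np.isfinite(b), b, 0.0
    ) > 0
    prob = np.where(mid_positive, flipped, direct)
    return np.maximum(prob, _PROB_FLOOR)


def _validate_inputs(outcome: np.ndarray, weights: np.ndarray) -> None:
    if not np.isin(outcome, np.arange(1, N_LEVELS + 1)).all():
        raise ValueError("outcome levels must lie in 1..5")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")


def log_likelihood(
    params: HopitParams,
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Survey-weighted log-likelihood of the observed levels."""
    outcome = np.asarray(outcome, dtype=int)
    weights = np.asarray(weights, dtype=float)
    _validate_inputs(outcome, weights)
    xb = latent_index(params, latent)
    tau = thresholds(params, threshold)
    a, b = _interval_bounds(tau, xb, outcome)
    return float(np.sum(weights * np.log(_interval_prob(a, b))))


def score(
    params: HopitParams,
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Analytic gradient of the weighted log-likelihood over (beta, lambda, gamma).

    The cut-point chain rule: tau_m depends on eta_k = lambda_k + gamma_k'z
    for every k <= m, with d tau_m / d eta_1 = 1 and
    d tau_m / d eta_k = exp(eta_k) for k >= 2.
    """
    rows_grad, _ = _score_rows(params, latent, threshold, outcome, weights)
    return rows_grad.sum(axis=0)


def _score_rows(
    params: HopitParams,
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row weighted score contributions, shape (n, n_free)."""
    outcome = np.asarray(outcome, dtype=int)
    weights = np.asarray(weights, dtype=float)
    _validate_inputs(outcome, weights)
    X, Z = latent.matrix, threshold.matrix
    n = X.shape[0]
    xb = latent_index(params, latent)
    eta = _eta(params, threshold)
    tau = thresholds(params, threshold)
    a, b = _interval_bounds(tau, xb, outcome)
    prob = _interval_prob(a, b)

    phi_a = np.where(np.isfinite(a), np.exp(-0.5 * np.square(np.where(np.isfinite(a), a, 0.0))) / np.sqrt(2 * np.pi), 0.0)
    phi_b = np.where(np.isfinite(b), np.exp(-0.5 * np.square(np.where(np.isfinite(b), b, 0.0))) / np.sqrt(2 * np.pi), 0.0)

    u = phi_a / prob          # d lnP / d tau_upper (zero when upper is +inf)
    l = -phi_b / prob         # d lnP / d tau_lower (zero when lower is -inf)

    # beta block: d lnP / d beta = (phi(b) - phi(a)) / P * x
    beta_coef = (phi_b - phi_a) / prob
    grad_beta = (weights * beta_coef)[:, None] * X

    # eta blocks: d tau_m / d eta_k = [k <= m] * d_k, d_1 = 1, d_k = exp(eta_k)
    ks = np.arange(1, N_CUTS + 1)[None, :]          # (1, 4)
    in_upper = (ks <= outcome[:, None]) & (outcome[:, None] <= N_CUTS)
    in_lower = ks <= (outcome[:, None] - 1)
    d = np.ones((n, N_CUTS))
    d[:, 1:] = np.exp(np.clip(eta[:, 1:], -_EXP_CLIP, _EXP_CLIP))
    g_eta = (u[:, None] * in_upper + l[:, None] * in_lower) * d  # (n, 4)
    wg = weights[:, None] * g_eta
    grad_lam = wg
    # gamma block: for each cut j, gradient over z columns is wg[:, j] * z
    grad_gamma = wg[:, :, None] * Z[:, None, :]      # (n, 4, q)

    per_row = np.concatenate(
        [grad_beta, grad_lam, grad_gamma.reshape(n, -1)], axis=1
    )
    return per_row, prob


def category_probabilities(
    params: HopitParams,
    latent: LatentDesign,
    threshold: ThresholdDesign,
) -> np.ndarray:
    """Per-row probabilities of each of the five levels, shape (n, 5)."""
    xb = latent_index(params, latent)
    tau = thresholds(params, threshold)
    n = tau.shape[0]
    cdf = np.column_stack(
        [np.zeros(n), ndtr(tau - xb[:, None]), np.ones(n)]
    )
    return np.diff(cdf, axis=1)


@dataclass
class FittedHopit:
    """A fitted model: estimates, covariance, and fit diagnostics."""

    params: HopitParams
    vcov: np.ndarray
    loglik: float
    loglik_null: float
    n_obs: int
    sum_weights: float
    converged: bool
    dimension: str = ""
    n_iter: int = 0
    gradient_norm: float = np.nan
    parameter_names: list[str] = field(default_factory=list)
    latent_names: tuple[str, ...] = ()
    threshold_names: tuple[str, ...] = ()
    group_block: tuple[str, ...] = ()

    @property
    def n_free(self) -> int:
        return self.params.n_free

    def to_json(self, path) -> None:
        payload = {
            "dimension": self.dimension,
            "parameter_names": self.parameter_names,
            "estimates": self.params.pack().tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n_obs": self.n_obs,
            "sum_weights": self.sum_weights,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "gradient_norm": self.gradient_norm,
            "latent_names": list(self.latent_names),
            "threshold_names": list(self.threshold_names),
            "group_block": list(self.group_block),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedHopit":
        with open(path) as fh:
            d = json.load(fh)
        p = len(d["latent_names"])
        q = len(d["threshold_names"])
        params = HopitParams.unpack(np.asarray(d["estimates"]), p, q)
        return cls(
            params=params,
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=d["loglik"],
            loglik_null=d["loglik_null"],
            n_obs=d["n_obs"],
            sum_weights=d["sum_weights"],
            converged=d["converged"],
            dimension=d["dimension"],
            n_iter=d["n_iter"],
            gradient_norm=d["gradient_norm"],
            parameter_names=d["parameter_names"],
            latent_names=tuple(d["latent_names"]),
            threshold_names=tuple(d["threshold_names"]),
            group_block=tuple(d["group_block"]),
        )


def _starting_values(
    p: int, q: int, outcome: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Deterministic start: beta = gamma = 0; lambda from the weighted
    cumulative outcome distribution via the probit quantile function."""
    shares = np.array(
        [weights[outcome == j].sum() for j in range(1, N_LEVELS + 1)]
    ) / weights.sum()
    cum = np.clip(np.cumsum(shares)[:N_CUTS], 1e-6, 1 - 1e-6)
    cum = np.maximum.accumulate(cum)
    tau0 = ndtri(cum)
    # keep increments bounded away from zero so log() is finite
    incr = np.maximum(np.diff(tau0), 1e-3)
    lam0 = np.concatenate([[tau0[0]], np.log(incr)])
    theta0 = np.zeros(p + N_CUTS + N_CUTS * q)
    theta0[p : p + N_CUTS] = lam0
    return theta0


def _numerical_hessian(fun_grad, theta: np.ndarray) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h
        tm[i] -= h
        H[:, i] = (fun_grad(tp) - fun_grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def _empty_threshold_design(n: int) -> ThresholdDesign:
    return ThresholdDesign(
        matrix=np.empty((n, 0)), column_names=(), group_block=()
    )


def _empty_latent_design(n: int) -> LatentDesign:
    return LatentDesign(
        matrix=np.empty((n, 0)), column_names=(), provenance=()
    )


def _maximize(
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray,
    gtol: float,
    maxiter: int,
):
    p, q = latent.n_columns, threshold.n_columns

    def negll_grad(theta: np.ndarray):
        params = HopitParams.unpack(theta, p, q)
        per_row, prob = _score_rows(params, latent, threshold, outcome, weights)
        nll = -float(np.sum(weights * np.log(prob)))
        return nll, -per_row.sum(axis=0)

    theta0 = _starting_values(p, q, outcome, weights)
    res = optimize.minimize(
        negll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    if not res.success:
        # quasi-Newton occasionally stalls on flat likelihoods; restart once
        # from the best point found, then fall back to derivative-free
        res2 = optimize.minimize(
            negll_grad, res.x, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            res3 = optimize.minimize(
                lambda t: negll_grad(t)[0], res.x, method="Nelder-Mead",
                options={"maxiter": 5000, "fatol": 1e-10, "xatol": 1e-8},
            )
            if res3.fun < res.fun:
                res3.jac = negll_grad(res3.x)[1]
                res = res3
    return res, negll_grad


def fit(
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray | None = None,
    dimension: str = "",
    gtol: float = 1e-6,
    maxiter: int = 2000,
    vcov_type: str = "observed_information",
    fit_null: bool = True,
) -> FittedHopit:
    """Fit the two-equation ordered probit by weighted maximum likelihood.

    Starting values are deterministic (zero slopes; cut-point intercepts
    matched to the weighted outcome distribution), so refits on identical
    inputs reproduce identical estimates. The covariance matrix is the
    inverse observed information at the optimum by default;
    ``vcov_type="sandwich"`` gives the design-based estimator
    ``A^{-1} B A^{-1}`` with ``B`` the outer product of per-row weighted
    scores, appropriate when weights make the information model-based.
    Also fits the weighted intercept-only ordered probit for the null
    log-likelihood used by fit indices.
    """
    outcome = np.asarray(outcome, dtype=int)
    n = outcome.size
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    _validate_inputs(outcome, weights)
    _check_disjoint(latent.column_names, threshold.column_names)

    observed_levels = np.unique(outcome)
    if observed_levels.size < N_LEVELS:
        missing = sorted(set(range(1, N_LEVELS + 1)) - set(observed_levels))
        warnings.warn(
            f"outcome levels {missing} unobserved; the adjacent threshold "
            "region is weakly identified",
            RuntimeWarning,
            stacklevel=2,
        )

    p, q = latent.n_columns, threshold.n_columns
    res, negll_grad = _maximize(latent, threshold, outcome, weights, gtol, maxiter)
    theta_hat = res.x

    H = _numerical_hessian(lambda t: negll_grad(t)[1], theta_hat)
    # Newton polish: quasi-Newton stops at ftol precision (~1e-6 in the
    # parameters); a few Newton steps restricted to well-identified
    # directions sharpen the optimum to near machine precision
    eigval_h, eigvec_h = np.linalg.eigh(H)
    ident = eigval_h > 1e-9 * max(eigval_h.max(), 1.0)
    nll_cur, g_cur = negll_grad(theta_hat)
    for _ in range(3):
        coef = eigvec_h.T @ g_cur
        step = eigvec_h @ np.where(ident, coef / np.where(ident, eigval_h, 1.0), 0.0)
        cand = theta_hat - step
        nll_new, g_new = negll_grad(cand)
        if nll_new <= nll_cur and np.max(np.abs(g_new)) < np.max(np.abs(g_cur)):
            theta_hat, nll_cur, g_cur = cand, nll_new, g_new
        else:
            break
    params = HopitParams.unpack(theta_hat, p, q)
    loglik = -float(nll_cur)
    grad_norm = float(np.max(np.abs(g_cur)))
    # gradient tolerance scales with the likelihood magnitude: a weighted
    # lnL of order 1e5 cannot be driven to an absolute 1e-6 gradient
    converged = grad_norm < 1e-4 * (1.0 + abs(nll_cur))
    if not converged:
        warnings.warn(
            f"optimizer did not fully converge (grad max-norm {grad_norm:.2e}); "
            "returning partial results",
            RuntimeWarning,
            stacklevel=2,
        )
    # invert through the eigendecomposition with a floor: near-unidentified
    # directions (e.g. a cut-point slope for a nearly empty cell) then get
    # very large but positive variances instead of an indefinite inverse
    eigval, eigvec = eigval_h, eigvec_h
    floor = max(eigval.max(), 1.0) * 1e-10
    if (eigval < floor).any():
        warnings.warn(
            "observed information is nearly singular; some variances are "
            "floored-eigenvalue approximations",
            RuntimeWarning,
            stacklevel=2,
        )
        eigval = np.maximum(eigval, floor)
    A_inv = (eigvec / eigval) @ eigvec.T
    if vcov_type == "observed_information":
        vcov = A_inv
    elif vcov_type == "sandwich":
        per_row, _ = _score_rows(params, latent, threshold, outcome, weights)
        B = per_row.T @ per_row
        vcov = A_inv @ B @ A_inv
    else:
        raise ValueError(f"unknown vcov_type {vcov_type!r}")
    vcov = 0.5 * (vcov + vcov.T)

    # null model: intercept-only ordered probit (lambda free, nothing else)
    if fit_null:
        null_res, _ = _maximize(
            _empty_latent_design(n), _empty_threshold_design(n), outcome,
            weights, gtol, maxiter,
        )
        loglik_null = -float(null_res.fun)
    else:
        loglik_null = np.nan

    logger.info(
        "fit %s: lnL=%.3f, null lnL=%.3f, %d iters, grad norm %.2e",
        dimension or "<unnamed>", loglik, loglik_null,
        getattr(res, "nit", -1), grad_norm,
    )
    return FittedHopit(
        params=params,
        vcov=vcov,
        loglik=loglik,
        loglik_null=loglik_null,
        n_obs=n,
        sum_weights=float(weights.sum()),
        converged=converged,
        dimension=dimension,
        n_iter=int(getattr(res, "nit", -1)),
        gradient_norm=grad_norm,
        parameter_names=params.parameter_names(latent, threshold),
        latent_names=latent.column_names,
        threshold_names=threshold.column_names,
        group_block=threshold.group_block,
    )
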