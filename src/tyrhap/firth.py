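"""Firth bias-reduced logistic regression.

Maximizes the Jeffreys-prior penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),

where I(beta) = X'WX is the Fisher information of the logistic model and
W = diag(pi_i (1 - pi_i)).  The penalty removes the O(1/n) bias of the MLE
and — crucially for sparse case-control cells — guarantees finite estimates
under complete or quasi-complete separation.

Newton iterations use the modified score

    U*_j(beta) = U_j(beta) + 1/2 sum_i h_i (1/2 - pi_i) x_ij,

with h_i the hat-matrix diagonals of W^1/2 X (X'WX)^-1 X' W^1/2, and
step-halving to enforce monotone ascent of l*.  Confidence intervals default
to profile penalized likelihood (Wald available), and hypothesis tests are
penalized likelihood-ratio (PLR) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""


@dataclass
class FirthModel:
    """A converged penalized-likelihood fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    penalized_loglik: float
    iterations: int
    converged: bool
    design_labels: list[str]
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def wald_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval on the odds-ratio scale.

    ``lower_open`` / ``upper_open`` flag bounds that could not be bracketed
    within +-15 on the log-odds scale (reported as unbounded, not raised).
    """

    level: float
    lower: float
    upper: float
    method: str  # "profile_penalized" | "wald"
    lower_open: bool = False
    upper_open: bool = False


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d design matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    if n < p:
        raise ValueError("need at least as many observations as parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify near-dependent columns from the QR R-diagonal
        _, R = np.linalg.qr(X)
        d = np.abs(np.diag(R))
        bad = [j for j in range(p) if d[j] < 1e-8 * max(d.max(), 1.0)]
        raise SingularDesignError(f"rank-deficient design (rank {rank} < {p}); suspect columns {bad}")
    return X, y


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pi = expit(eta)
    w = np.clip(pi * (1.0 - pi), 1e-300, None)
    XtWX = X.T @ (X * w[:, None])
    # Cholesky log-determinant for stability; an (effectively) singular
    # information at an extreme trial point means l* -> -inf there, which
    # step-halving then rejects.
    try:
        L = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return -np.inf
    return ll + float(np.log(np.diag(L)).sum())


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    fixed: Optional[Mapping[int, float]] = None,
    beta0: Optional[np.ndarray] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    max_halvings: int = 25,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """Core Newton loop; ``fixed`` pins coefficients (profile likelihood).

    The penalty always uses the information of the FULL design, as the
    profile penalized likelihood requires.
    """
    n, p = X.shape
    fixed = dict(fixed or {})
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    for j, v in fixed.items():
        beta[j] = v
    ll = _penalized_loglik(X, y, beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = expit(eta)
        w = np.clip(pi * (1.0 - pi), 1e-300, None)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by _validate
            raise SingularDesignError(str(exc)) from exc
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, Xw)
        score = X.T @ (y - pi + h * (0.5 - pi))
        if free.size == 0:
            converged = True
            break
        step = np.zeros(p)
        sub = XtWX[np.ix_(free, free)]
        step[free] = np.linalg.solve(sub, score[free])
        # step-halving: enforce ascent of the penalized log-likelihood
        scale = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + scale * step
            ll_new = _penalized_loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            cand, ll_new = beta, ll
        delta = np.max(np.abs(cand - beta)) if free.size else 0.0
        beta, ll = cand, max(ll_new, ll)
        trace.append(ll)
        if delta < tol:
            converged = True
            break
    eta = X @ beta
    pi = expit(eta)
    w = np.clip(pi * (1.0 - pi), 1e-300, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, ll, it, converged, trace


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    labels: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    max_halvings: int = 25,
) -> FirthModel:
    """Fit the Firth-penalized logistic model.

    ``X`` must include the intercept column.  Estimates are finite for any
    data, including complete separation.
    """
    X, y = _validate(X, y)
    beta, cov, ll, it, converged, trace = _fit(
        X, y, max_iter=max_iter, tol=tol, max_halvings=max_halvings
    )
    return FirthModel(
        coefficients=beta,
        covariance=cov,
        penalized_loglik=ll,
        iterations=it,
        converged=converged,
        design_labels=list(labels) if labels is not None else [f"x{j}" for j in range(X.shape[1])],
        loglik_trace=trace,
    )


def _profile_loglik(X, y, j, value, beta_start):
    beta, _, ll, _, _, _ = _fit(X, y, fixed={j: value}, beta0=beta_start)
    return ll, beta


def profile_ci(
    model: FirthModel,
    X: np.ndarray,
    y: np.ndarray,
    j: int,
    level: float = 0.95,
    max_abs: float = 15.0,
) -> IntervalEstimate:
    """Profile-penalized-likelihood CI for coefficient ``j`` (OR scale).

    The bounds solve 2[l*(beta_hat) - l*_profile(b)] = chi2_{1,level},
    found by outward bracketing then Brent root refinement.  A root not
    bracketed within +-``max_abs`` log-odds is reported as an open
    (unbounded) side rather than raising.
    """
    X, y = _validate(X, y)
    target = stats.chi2.ppf(level, 1)
    ll_max = model.penalized_loglik
    bhat = model.coefficients[j]
    se = model.wald_se()[j]
    if not np.isfinite(se) or se <= 0:
        se = 0.5

    def deficit(b: float, start: np.ndarray) -> tuple[float, np.ndarray]:
        ll, beta = _profile_loglik(X, y, j, b, start)
        return 2.0 * (ll_max - ll) - target, beta

    bounds = {}
    open_flags = {}
    for side, direction in (("lower", -1.0), ("upper", +1.0)):
        step = max(se, 0.25)
        b_in, f_in = bhat, -target  # deficit at the estimate
        start = model.coefficients.copy()
        b_out = None
        b = bhat
        while abs(b - bhat) < max_abs:
            b = b + direction * step
            f, beta_b = deficit(b, start)
            start = beta_b
            if f > 0:
                b_out, f_out = b, f
                break
            b_in, f_in = b, f
            step *= 1.6
        if b_out is None:
            bounds[side] = -np.inf if direction < 0 else np.inf
            open_flags[side] = True
            continue
        # Brent on the bracket [b_in, b_out] (deficit changes sign)
        from scipy.optimize import brentq

        warm = {"beta": start}

        def g(b):
            f, beta_b = deficit(b, warm["beta"])
            warm["beta"] = beta_b
            return f

        lo, hi = sorted((b_in, b_out))
        root = brentq(g, lo, hi, xtol=1e-6)
        bounds[side] = root
        open_flags[side] = False
    return IntervalEstimate(
        level=level,
        lower=float(np.exp(bounds["lower"])),
        upper=float(np.exp(bounds["upper"])),
        method="profile_penalized",
        lower_open=open_flags["lower"],
        upper_open=open_flags["upper"],
    )


def wald_ci(model: FirthModel, j: int, level: float = 0.95) -> IntervalEstimate:
    z = stats.norm.ppf(0.5 + level / 2.0)
    b, se = model.coefficients[j], model.wald_se()[j]
    return IntervalEstimate(
        level=level,
        lower=float(np.exp(b - z * se)),
        upper=float(np.exp(b + z * se)),
        method="wald",
    )


def plr_test(model: FirthModel, X: np.ndarray, y: np.ndarray, j: int) -> float:
    """Penalized likelihood-ratio p-value for H0: beta_j = 0."""
    stat = plr_statistic(model, X, y, j)
    return float(stats.chi2.sf(stat, 1))


def plr_statistic(model: FirthModel, X: np.ndarray, y: np.ndarray, j: int) -> float:
    """The 1-df PLR chi-square statistic for H0: beta_j = 0."""
    X, y = _validate(X, y)
    start = model.coefficients.copy()
    start[j] = 0.0
    _, _, ll0, _, _, _ = _fit(X, y, fixed={j: 0.0}, beta0=start)
    return max(0.0, 2.0 * (model.penalized_loglik - ll0))


def fit_logistic_mle(
    X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Plain (unpenalized) logistic MLE by Newton; used for bias comparisons.

    Under separation the estimates diverge; the returned flag is ``False``
    when the iteration hit the cap or produced non-finite values.
    """
    X, y = _validate(X, y)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = np.clip(pi * (1.0 - pi), 1e-12, None)
        score = X.T @ (y - pi)
        try:
            step = np.linalg.solve(X.T @ (X * w[:, None]), score)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
            return beta, False
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False
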