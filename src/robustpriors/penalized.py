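"""Penalized regression toward a non-zero prior.

The generalized ridge objective

    min_w  ||y - X w||^2  +  theta ||w - w_prior||^2

has the closed-form solution (X'X + theta I)^{-1} (X'y + theta w_prior):
theta = 0 recovers OLS and theta -> inf drives the weights to the prior.
The logistic analogue maximizes the Bernoulli log-likelihood minus
(theta/2)||w - w_prior||^2 by damped Newton-Raphson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .priors import PriorSpec, zero_prior

__all__ = [
    "PenalizedFit",
    "ols_fit",
    "ridge_fit",
    "ridge_path",
    "logistic_ridge_fit",
    "predict_choice",
]


@dataclass
class PenalizedFit:
    """Estimated weights together with the penalty and prior that produced them."""

    weights: np.ndarray
    theta: float
    prior: PriorSpec
    solver_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta < 0:
            raise ValueError("theta must be >= 0")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "theta": self.theta,
                "family": self.prior.family,
                "solver_info": self.solver_info,
            }
        )


def ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares weights (pseudoinverse; rank-deficient OK)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return w


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    theta: float,
    prior: PriorSpec | np.ndarray | None = None,
) -> PenalizedFit:
    """Solve the generalized ridge problem in closed form.

    ``prior`` may be a PriorSpec, a raw vector (treated as a custom prior),
    or None for the zero prior. X must already be in the prior's design
    space (apply the TTB transform first where applicable).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta < 0:
        raise ValueError("theta must be >= 0")
    m = X.shape[1]
    if prior is None:
        prior = zero_prior(m)
    elif not isinstance(prior, PriorSpec):
        prior = PriorSpec(np.asarray(prior, dtype=float), family="custom")
    if prior.m != m:
        raise ValueError("prior length does not match design columns")
    if theta == 0.0:
        w = ols_fit(X, y)
    elif np.isinf(theta):
        # exact shrinkage limit: the penalty dominates and w -> w_prior
        w = prior.w_prior.copy()
    else:
        A = X.T @ X + theta * np.eye(m)
        b = X.T @ y + theta * prior.w_prior
        w = np.linalg.solve(A, b)
    return PenalizedFit(w, float(theta), prior, {"method": "closed_form"})


def ridge_path(
    X: np.ndarray,
    y: np.ndarray,
    thetas: np.ndarray,
    prior: PriorSpec | np.ndarray | None = None,
) -> np.ndarray:
    """Weights for every theta on a grid, via one eigendecomposition of X'X.

    Returns an array of shape (len(thetas), m). theta = 0 entries fall back
    to the minimum-norm OLS solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if np.any(thetas < 0):
        raise ValueError("theta must be >= 0")
    m = X.shape[1]
    wp = (prior.w_prior if isinstance(prior, PriorSpec)
          else np.zeros(m) if prior is None else np.asarray(prior, dtype=float))
    lam, V = np.linalg.eigh(X.T @ X)
    bx = V.T @ (X.T @ y)
    bp = V.T @ wp
    finite = np.where(np.isinf(thetas), 1.0, thetas)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = (bx[None, :] + finite[:, None] * bp[None, :]) / (lam[None, :] + finite[:, None])
    W = coef @ V.T
    for i in np.nonzero(thetas == 0)[0]:
        W[i] = ols_fit(X, y)
    for i in np.nonzero(np.isinf(thetas))[0]:
        W[i] = wp  # exact shrinkage limit
    return W


def _logistic_mu(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _penalized_loglik(
    w: np.ndarray, X: np.ndarray, y01: np.ndarray, theta: float, wp: np.ndarray
) -> float:
    eta = X @ w
    ll = float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))
    return ll - 0.5 * theta * float(np.sum((w - wp) ** 2))


def logistic_ridge_fit(
    X: np.ndarray,
    y01: np.ndarray,
    theta: float,
    prior: PriorSpec | np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PenalizedFit:
    """Penalized logistic regression by damped Newton-Raphson.

    Maximizes loglik(w) - (theta/2)||w - w_prior||^2. Iterations start at the
    prior, take Newton steps w += (X'SX + theta I)^{-1} grad with
    S = diag(mu(1-mu)), and halve the step while the objective decreases.
    Convergence is declared when the gradient infinity-norm falls below
    ``tol``; hitting ``max_iter`` flags ``converged=False`` but is not fatal.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not np.isin(y01, (0.0, 1.0)).all():
        raise ValueError("y01 must be coded {0, 1}")
    m = X.shape[1]
    if prior is None:
        prior = zero_prior(m)
    elif not isinstance(prior, PriorSpec):
        prior = PriorSpec(np.asarray(prior, dtype=float), family="custom")
    wp = prior.w_prior
    if np.isinf(theta):
        return PenalizedFit(wp.copy(), theta, prior,
                            {"iterations": 0, "converged": True, "limit": True})
    w = wp.copy()
    obj = _penalized_loglik(w, X, y01, theta, wp)
    gnorm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _logistic_mu(X @ w)
        grad = X.T @ (y01 - mu) - theta * (w - wp)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm <= tol:
            converged = True
            break
        S = mu * (1.0 - mu)
        H = (X.T * S) @ X + theta * np.eye(m)
        # ridge the Hessian if numerically singular (theta = 0, flat mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-10 * np.eye(m), grad)
        t = 1.0
        for _ in range(50):
            w_new = w + t * step
            obj_new = _penalized_loglik(w_new, X, y01, theta, wp)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        else:
            break  # no acceptable step; stop with current iterate
        w, obj = w_new, obj_new
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite objective at iteration {it}: {obj}")
    return PenalizedFit(
        w,
        float(theta),
        prior,
        {"iterations": it, "grad_norm": gnorm, "converged": converged, "objective": obj},
    )


def predict_choice(
    fit: PenalizedFit,
    X_new: np.ndarray,
    task: str = "sign",
    rng: np.random.Generator | None = None,
    is_transformed: bool = False,
) -> np.ndarray:
    """Predict choices (sign task) or labels (probability task) for new rows.

    X_new must already carry the prior's design transform when the fit used
    one (pass ``prior.apply_transform(X_raw)`` and set ``is_transformed``);
    a non-identity transform with ``is_transformed=False`` is an error, since
    the mismatch is undetectable from shapes alone. Zero scores in the sign
    task break randomly with probability 1/2 each way, matching the
    heuristics' tie rule; the probability task thresholds the logistic mean
    at 0.5.
    """
    X_new = np.asarray(X_new, dtype=float)
    if fit.prior.transform != "identity" and not is_transformed:
        raise ValueError(
            "fit uses a non-identity design transform; apply "
            "fit.prior.apply_transform to X_new and pass is_transformed=True"
        )
    if X_new.shape[1] != fit.m:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns but fit has {fit.m} weights"
        )
    score = X_new @ fit.weights
    if task == "sign":
        pred = np.sign(score)
        ties = pred == 0
        if ties.any():
            if rng is None:
                raise ValueError("rng required to break tied (zero-score) predictions")
            pred[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        return pred
    if task == "probability":
        return (_logistic_mu(score) >= 0.5).astype(float) * 2.0 - 1.0
    raise ValueError(f"unknown task {task!r}")
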