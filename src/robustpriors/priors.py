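"""Construction of non-zero prior weight vectors for penalized regression.

Each prior is a point estimate from a constrained (heuristic-style) model:

* TAL prior — a single least-squares scalar shared by all cues, signed by
  the cue directions q, so all weights have equal magnitude.
* TTB prior — the same construction after rescaling the design columns by a
  geometric progression phi**rank (phi = 2 by default), which encodes the
  validity ranking non-compensatorily; the penalized model then also runs on
  the transformed design.
* logistic prior — the 1-D maximum-likelihood scalar of a logistic model
  with weights constrained to q * w, used for logistic-ridge fits.
* permuted-OLS prior — an ad-hoc non-zero control: the OLS solution with
  entries randomly permuted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PriorSpec",
    "ttb_transform",
    "fit_scale_prior",
    "fit_logistic_scale_prior",
    "permuted_ols_prior",
    "zero_prior",
]

#: Geometric base of the TTB design transform.
DEFAULT_PHI = 2.0

#: Bound on the logistic scale parameter; hit under complete separation.
LOGISTIC_SCALE_BOUND = 50.0


@dataclass
class PriorSpec:
    """A prior weight vector plus the design transform it is valid under.

    ``transform`` is ``"identity"`` or ``"ttb"``; in the latter case the
    penalized model must be fit (and must predict) on ``apply_transform(X)``,
    i.e. the design with column j scaled by phi**rank_j.
    """

    w_prior: np.ndarray
    family: Literal["zero", "tal", "ttb", "ols_permuted", "logistic_tal", "custom"]
    transform: Literal["identity", "ttb"] = "identity"
    phi: float = 1.0
    ranks: np.ndarray | None = None
    scale: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w_prior = np.asarray(self.w_prior, dtype=float)
        if not np.isfinite(self.w_prior).all():
            raise ValueError("prior weights must be finite")
        if self.transform == "ttb" and self.ranks is None:
            raise ValueError("ttb transform requires ranks")

    @property
    def m(self) -> int:
        return self.w_prior.shape[0]

    def apply_transform(self, X: np.ndarray) -> np.ndarray:
        """Map a raw design matrix into the space the prior lives in."""
        if self.transform == "identity":
            return np.asarray(X, dtype=float)
        return ttb_transform(X, self.ranks, self.phi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "w_prior": self.w_prior.tolist(),
                "family": self.family,
                "transform": self.transform,
                "phi": self.phi,
                "ranks": None if self.ranks is None else np.asarray(self.ranks).tolist(),
                "scale": self.scale,
                "diagnostics": self.diagnostics,
            }
        )


def ttb_transform(X: np.ndarray, ranks: np.ndarray, phi: float = DEFAULT_PHI) -> np.ndarray:
    """Scale design column j by phi**rank_j (phi = 1 leaves X unchanged)."""
    X = np.asarray(X, dtype=float)
    ranks = np.asarray(ranks)
    if phi < 1:
        raise ValueError("phi must be >= 1")
    if ranks.shape[0] != X.shape[1]:
        raise ValueError("ranks length must match design columns")
    return X * (float(phi) ** ranks)[None, :]


def zero_prior(m: int) -> PriorSpec:
    """The all-zeros prior of standard ridge regression."""
    return PriorSpec(np.zeros(m), family="zero")


def fit_scale_prior(
    X_design: np.ndarray,
    y: np.ndarray,
    q: np.ndarray,
    family: Literal["tal", "ttb"] = "tal",
    ranks: np.ndarray | None = None,
    phi: float = DEFAULT_PHI,
) -> PriorSpec:
    """Least-squares scalar shared across cues: min_w ||y - X_design (q w)||^2.

    Solved in closed form as ((X_design q)' y) / ||X_design q||^2; the prior
    vector is q * scale. For the TTB family pass the transformed design and
    the ranks so the resulting spec carries its transform.
    """
    X_design = np.asarray(X_design, dtype=float)
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if not np.any(q):
        raise ValueError("cue directions are all zero; no prior direction to scale")
    z = X_design @ q
    nrm2 = float(z @ z)
    if nrm2 == 0.0:
        warnings.warn("X_design @ q is the zero vector; prior scale set to 0")
        scale = 0.0
    else:
        scale = float(z @ y) / nrm2
    spec_kwargs: dict = {"scale": scale}
    if family == "ttb":
        spec_kwargs.update(transform="ttb", phi=phi, ranks=np.asarray(ranks))
    return PriorSpec(q * scale, family=family, **spec_kwargs)


def _logistic_nll(w: float, z: np.ndarray, y01: np.ndarray) -> float:
    eta = w * z
    # log(1 + exp(eta)) - y*eta, numerically stabilized
    return float(np.sum(np.logaddexp(0.0, eta) - y01 * eta))


def fit_logistic_scale_prior(
    X: np.ndarray,
    y01: np.ndarray,
    q: np.ndarray,
    bound: float = LOGISTIC_SCALE_BOUND,
) -> PriorSpec:
    """1-D maximum-likelihood logistic scalar with weights constrained to q*w.

    The prior vector is q * |w_hat|; the absolute value guarantees the prior
    points in the cue directions. The scalar search is bounded (|w| <= 50)
    so complete separation saturates instead of diverging; saturation is
    flagged in ``diagnostics``.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    q = np.asarray(q, dtype=float)
    classes = np.unique(y01)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y01 must be coded {0, 1}")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    z = X @ q
    res = minimize_scalar(
        _logistic_nll, bounds=(-bound, bound), args=(z, y01), method="bounded",
        options={"xatol": 1e-10},
    )
    scale = float(res.x)
    at_bound = bool(abs(scale) >= bound - 1e-6)
    if at_bound:
        warnings.warn("logistic prior scale hit the search bound (separated data)")
    return PriorSpec(
        q * abs(scale),
        family="logistic_tal",
        scale=abs(scale),
        diagnostics={"raw_scale": scale, "at_bound": at_bound, "nll": float(res.fun)},
    )


def permuted_ols_prior(X: np.ndarray, y: np.ndarray, seed: int | None = 0) -> PriorSpec:
    """OLS weights with entries permuted at random — a non-heuristic control."""
    from .penalized import ols_fit

    w = ols_fit(X, y)
    rng = np.random.default_rng(seed)
    return PriorSpec(w[rng.permutation(w.shape[0])], family="ols_permuted")
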