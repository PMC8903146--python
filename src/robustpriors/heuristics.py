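"""Cue validities and the tallying (TAL) and take-the-best (TTB) heuristics.

A cue's validity v = (R - W) / (R + W) is its signed accuracy among the rows
where it discriminates (x != 0); rows with x = 0 present no prediction and
are ignored. TAL is a majority vote over cue-direction votes sign(v_j x_j);
TTB decides by the single discriminating cue with the largest |v|. When no
cue provides evidence, both choose randomly with probability 1/2 per option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import DecisionDataset

__all__ = ["HeuristicModel", "cue_validity", "fit_heuristic", "predict_tal", "predict_ttb"]


@dataclass
class HeuristicModel:
    """Per-cue validities with the derived quantities the heuristics use.

    directions q_j = sign(v_j); ranks r_j = #{j': |v_j'| < |v_j|} are
    ascending ranks of the absolute validities (tied magnitudes share a
    rank, and the weakest cues have rank 0).
    """

    validities: np.ndarray
    right: np.ndarray
    wrong: np.ndarray

    def __post_init__(self) -> None:
        self.validities = np.asarray(self.validities, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.wrong = np.asarray(self.wrong, dtype=float)
        if np.any(np.abs(self.validities) > 1 + 1e-12):
            raise ValueError("validities must lie in [-1, 1]")

    @property
    def m(self) -> int:
        return self.validities.shape[0]

    @property
    def directions(self) -> np.ndarray:
        return np.sign(self.validities)

    @property
    def ranks(self) -> np.ndarray:
        a = np.abs(self.validities)
        return (a[None, :] < a[:, None]).sum(axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "validities": self.validities.tolist(),
                "directions": self.directions.tolist(),
                "ranks": self.ranks.tolist(),
                "right": self.right.tolist(),
                "wrong": self.wrong.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "HeuristicModel":
        d = json.loads(Path(text).read_text() if isinstance(text, Path) else text)
        return cls(np.array(d["validities"]), np.array(d["right"]), np.array(d["wrong"]))


def cue_validity(x_col: np.ndarray, y: np.ndarray) -> tuple[float, int, int]:
    """Validity of one cue: counts of right and wrong sign-predictions.

    Returns (v, R, W). A cue that never discriminates (R + W = 0) gets
    validity 0 by convention, so it is inert downstream.
    """
    x_col = np.asarray(x_col, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_col.shape != y.shape:
        raise ValueError("x_col and y lengths differ")
    active = x_col != 0
    R = int(np.sum(np.sign(x_col[active]) == np.sign(y[active])))
    W = int(active.sum()) - R
    v = 0.0 if R + W == 0 else (R - W) / (R + W)
    return v, R, W


def fit_heuristic(train: DecisionDataset) -> HeuristicModel:
    """Estimate validities for every cue on a training set."""
    if train.n == 0:
        raise ValueError("empty training set")
    out = [cue_validity(train.X[:, j], train.y) for j in range(train.m)]
    v, R, W = map(np.array, zip(*out))
    return HeuristicModel(v, R, W)


def _random_sign(rng: np.random.Generator, size: int | None = None):
    return rng.choice([-1.0, 1.0], size=size)


def _resolve_ties(pred: np.ndarray, rng, tie_signs) -> np.ndarray:
    ties = pred == 0
    if ties.any():
        if tie_signs is not None:
            pred[ties] = np.asarray(tie_signs, dtype=float)[ties]
        elif rng is not None:
            pred[ties] = _random_sign(rng, int(ties.sum()))
        else:
            raise ValueError("tied prediction: provide rng or tie_signs")
    return pred


def predict_tal(
    model: HeuristicModel,
    x: np.ndarray,
    rng: np.random.Generator | None = None,
    tie_signs: np.ndarray | None = None,
) -> float | np.ndarray:
    """Tallying prediction sign(sum_j sign(v_j x_j)); ties resolved at random.

    Accepts a single ternary cue vector or an (n, m) matrix of them. Ties
    draw fresh +/-1 coins from ``rng``, or use the pre-drawn per-row
    ``tie_signs`` (so several models can share one coin per comparison).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    score = np.sign(X * model.validities[None, :]).sum(axis=1)
    pred = _resolve_ties(np.sign(score), rng, tie_signs)
    return float(pred[0]) if single else pred


def predict_ttb(
    model: HeuristicModel,
    x: np.ndarray,
    rng: np.random.Generator | None = None,
    tie_signs: np.ndarray | None = None,
) -> float | np.ndarray:
    """Take-the-best prediction from the top-validity discriminating cue.

    The discriminating cue (x_j != 0) of maximal |v_j| decides via
    sign(q_j x_j); |v| ties break to the lowest column index. If no cue
    discriminates, the choice is random with probability 1/2 per option.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    absv = np.abs(model.validities)
    q = model.directions
    # mask non-discriminating cues out of the argmax; -1 < all |v|
    masked = np.where(X != 0, absv[None, :], -1.0)
    jstar = np.argmax(masked, axis=1)  # first max -> lowest index on ties
    rows = np.arange(X.shape[0])
    pred = np.sign(q[jstar] * X[rows, jstar])
    dead = masked[rows, jstar] < 0  # no discriminating cue at all
    pred[dead] = 0.0
    pred = _resolve_ties(pred, rng, tie_signs)
    return float(pred[0]) if single else pred
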