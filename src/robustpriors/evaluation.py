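"""Evaluation machinery: test accuracy, the compensatoriness diagnostic, and
Monte-Carlo penalty sweeps over train/test partitions.

The normalized Shannon entropy of a weight vector,

    H = -sum_j w~_j log2 w~_j / log2 m,   w~_j = |w_j| / (||w||_1 phi**r_j),

measures how compensatory a solution is: it peaks at 1 when the predictive
force of the weights is uniform (the tallying ideal) and falls toward 0 as a
single cue dominates. phi = 1 for zero- and TAL-prior models; phi = 2 with
the training validity ranks for the TTB-prior model, whose weights live in
the geometrically rescaled design space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DecisionDataset, SplitSpec, split_train_test
from .heuristics import fit_heuristic, predict_tal, predict_ttb
from .penalized import logistic_ridge_fit, ridge_path, _logistic_mu
from .priors import (
    DEFAULT_PHI,
    PriorSpec,
    fit_logistic_scale_prior,
    fit_scale_prior,
    permuted_ols_prior,
    ttb_transform,
    zero_prior,
)

__all__ = [
    "SweepResult",
    "accuracy",
    "normalized_entropy",
    "default_theta_grid",
    "run_sweep",
    "best_worst_summary",
]

FAMILIES = ("zero", "tal", "ttb", "ols_permuted")


def accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    """Fraction of predictions matching the outcomes."""
    pred = np.asarray(pred)
    y = np.asarray(y)
    if pred.shape != y.shape:
        raise ValueError("pred and y lengths differ")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean(pred == y))


def normalized_entropy(
    w: np.ndarray,
    ranks: np.ndarray | None = None,
    phi: float = 1.0,
    renormalize: bool = False,
) -> float:
    """Normalized Shannon entropy of a weight vector (see module docstring).

    For phi > 1 the rank-discounted shares are sub-normalized (they sum to
    less than 1); ``renormalize=True`` rescales them to a proper
    distribution first. An all-zero weight vector has no defined entropy and
    returns NaN with a warning.
    """
    w = np.asarray(w, dtype=float)
    m = w.shape[0]
    a = np.abs(w)
    if a.sum() == 0:
        warnings.warn("entropy undefined for an all-zero weight vector")
        return float("nan")
    if m < 2:
        warnings.warn("entropy normalization undefined for a single weight")
        return float("nan")
    disc = np.ones(m) if (phi == 1.0 or ranks is None) else float(phi) ** np.asarray(ranks)
    wt = a / (a.sum() * disc)
    if renormalize:
        wt = wt / wt.sum()
    nz = wt > 0
    h = -float(np.sum(wt[nz] * np.log2(wt[nz])))
    return h / np.log2(m)


def default_theta_grid(
    n_points: int = 30, lo: float = 1e-2, hi: float = 1e6, include_inf: bool = True
) -> np.ndarray:
    """{0}, log-spaced penalties, and (by default) the exact prior endpoint.

    theta = inf is solved exactly as w = w_prior, representing the shrinkage
    limit where the model coincides with its prior (the heuristic for
    heuristic priors; all-zero weights, hence chance predictions, for the
    zero prior).
    """
    grid = np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), n_points)])
    return np.concatenate([grid, [np.inf]]) if include_inf else grid


@dataclass
class SweepResult:
    """Tidy sweep records plus per-iteration heuristic baselines.

    ``records`` has one row per (family, theta, iteration) with test
    accuracy, normalized entropy of the fitted weights, and the prior scale;
    ``heuristic_records`` has one row per (rule, iteration).
    """

    records: pd.DataFrame
    heuristic_records: pd.DataFrame
    theta_grid: np.ndarray
    n_iterations: int

    def mean_accuracy(self) -> pd.DataFrame:
        return (
            self.records.groupby(["family", "theta"], as_index=False)["accuracy"].mean()
        )

    def mean_entropy_by_family(self) -> pd.Series:
        return self.records.groupby("family")["entropy"].mean()


def _build_prior(
    family: str,
    train: DecisionDataset,
    heur,
    model: str,
    phi: float,
    prior_seed,
) -> PriorSpec:
    q = heur.directions
    ranks = heur.ranks
    if family == "zero":
        return zero_prior(train.m)
    if family == "ols_permuted":
        return permuted_ols_prior(train.X, train.y, seed=prior_seed)
    if family == "tal":
        if model == "logistic":
            return fit_logistic_scale_prior(train.X, train.y01, q)
        return fit_scale_prior(train.X, train.y, q, family="tal")
    if family == "ttb":
        Xt = ttb_transform(train.X, ranks, phi)
        if model == "logistic":
            spec = fit_logistic_scale_prior(Xt, train.y01, q)
            return PriorSpec(
                spec.w_prior, family="ttb", transform="ttb", phi=phi, ranks=ranks,
                scale=spec.scale, diagnostics=spec.diagnostics,
            )
        return fit_scale_prior(Xt, train.y, q, family="ttb", ranks=ranks, phi=phi)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def run_sweep(
    data: DecisionDataset,
    families: tuple[str, ...] = FAMILIES,
    theta_grid: np.ndarray | None = None,
    n_iterations: int = 100,
    n_train: int = 50,
    seed: int = 0,
    model: str = "linear",
    phi: float = DEFAULT_PHI,
    include_heuristics: bool = True,
) -> SweepResult:
    """Monte-Carlo penalty sweep over seeded train/test partitions.

    On each iteration the data are split, the heuristic (validities,
    directions, ranks) and all priors are fit on the training rows, each
    family is fit at every penalty on the grid, and test accuracy plus the
    normalized entropy of the fitted weights are recorded. ``model`` selects
    the linear (closed-form ridge, sign predictions) or logistic
    (Newton-Raphson, thresholded mean) solver. The TAL and TTB heuristics
    themselves are scored on the same splits when ``include_heuristics``.
    """
    theta_grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    if theta_grid.size == 0:
        raise ValueError("theta grid is empty")
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    rows: list[dict] = []
    heur_rows: list[dict] = []
    for it in range(n_iterations):
        train, test = split_train_test(data, SplitSpec(n_train, seed, it))
        heur = fit_heuristic(train)
        tie_rng = np.random.default_rng(np.random.SeedSequence((seed, it, 7919)))
        # one coin per test comparison, shared by every model and heuristic,
        # so the theta -> inf endpoint reproduces its heuristic exactly
        tie_signs = tie_rng.choice([-1.0, 1.0], size=test.n)
        if include_heuristics:
            heur_rows.append(
                {"rule": "tal", "iteration": it,
                 "accuracy": accuracy(predict_tal(heur, test.X, tie_signs=tie_signs),
                                      test.y)}
            )
            heur_rows.append(
                {"rule": "ttb", "iteration": it,
                 "accuracy": accuracy(predict_ttb(heur, test.X, tie_signs=tie_signs),
                                      test.y)}
            )
        for family in families:
            try:
                prior = _build_prior(family, train, heur, model, phi, (seed, it, 13))
            except ValueError as exc:  # e.g. all-zero cue directions
                rows.extend(
                    {"family": family, "theta": float(th), "iteration": it,
                     "accuracy": np.nan, "entropy": np.nan, "scale": np.nan,
                     "error": str(exc)}
                    for th in theta_grid
                )
                continue
            Xtr = prior.apply_transform(train.X)
            Xte = prior.apply_transform(test.X)
            ent_phi = prior.phi if prior.transform == "ttb" else 1.0
            ent_ranks = prior.ranks if prior.transform == "ttb" else None
            if model == "linear":
                W = ridge_path(Xtr, train.y, theta_grid, prior)
                scores = Xte @ W.T  # (n_test, n_theta)
                preds = np.sign(scores)
                ties = preds == 0
                if ties.any():
                    preds = np.where(ties, tie_signs[:, None], preds)
                correct = preds == test.y[:, None]
                for k, th in enumerate(theta_grid):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ent = normalized_entropy(W[k], ent_ranks, ent_phi)
                    rows.append(
                        {"family": family, "theta": float(th), "iteration": it,
                         "accuracy": float(correct[:, k].mean()), "entropy": ent,
                         "scale": prior.scale}
                    )
            else:
                for th in theta_grid:
                    fit = logistic_ridge_fit(Xtr, train.y01, float(th), prior)
                    pred = np.where(_logistic_mu(Xte @ fit.weights) >= 0.5, 1.0, -1.0)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ent = normalized_entropy(fit.weights, ent_ranks, ent_phi)
                    rows.append(
                        {"family": family, "theta": float(th), "iteration": it,
                         "accuracy": accuracy(pred, test.y), "entropy": ent,
                         "scale": prior.scale}
                    )
    return SweepResult(
        records=pd.DataFrame(rows),
        heuristic_records=pd.DataFrame(heur_rows),
        theta_grid=theta_grid,
        n_iterations=n_iterations,
    )


def best_worst_summary(sweep: SweepResult) -> pd.DataFrame:
    """Per family: the penalties with the best and worst mean test accuracy."""
    mean = sweep.mean_accuracy()
    if mean.empty:
        raise ValueError("empty sweep")
    out = []
    for family, grp in mean.groupby("family"):
        best = grp.loc[grp["accuracy"].idxmax()]
        worst = grp.loc[grp["accuracy"].idxmin()]
        out.append(
            {"family": family,
             "best_theta": best["theta"], "best_accuracy": best["accuracy"],
             "worst_theta": worst["theta"], "worst_accuracy": worst["accuracy"]}
        )
    return pd.DataFrame(out)
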