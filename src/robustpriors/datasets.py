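"""Decision and classification datasets: coding, pairing, splitting, synthesis.

Tabular decision problems are coded into the ternary cue representation used
by the tallying (TAL) and take-the-best (TTB) heuristics: attributes are
median-split, and (for paired-comparison tasks) every pair of objects becomes
one row of signed attribute differences in {-1, 0, +1} with outcome y in
{-1, +1} indicating which object has the larger criterion value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawDataset",
    "DecisionDataset",
    "SplitSpec",
    "read_raw_csv",
    "median_split",
    "make_paired_comparisons",
    "make_classification",
    "generate_synthetic_task",
    "split_train_test",
]


@dataclass
class RawDataset:
    """A cleaned tabular dataset: one real criterion plus m real attributes.

    Rows with missing cells are removed before construction; ``n_dropped``
    records how many were removed.
    """

    criterion: np.ndarray
    attributes: np.ndarray
    names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.attributes = np.asarray(self.attributes, dtype=float)
        if self.attributes.ndim != 2:
            raise ValueError("attributes must be a 2-D array")
        n, m = self.attributes.shape
        if n < 2:
            raise ValueError("need at least 2 objects")
        if m < 1:
            raise ValueError("need at least 1 attribute")
        if self.criterion.shape != (n,):
            raise ValueError("criterion length must match attribute rows")
        if not (np.isfinite(self.criterion).all() and np.isfinite(self.attributes).all()):
            raise ValueError("RawDataset may not contain missing/non-finite values")
        if not self.names:
            self.names = [f"cue{j}" for j in range(m)]
        elif len(self.names) != m:
            raise ValueError("names length must match attribute columns")

    @property
    def n_objects(self) -> int:
        return self.attributes.shape[0]

    @property
    def n_cues(self) -> int:
        return self.attributes.shape[1]


@dataclass
class DecisionDataset:
    """Coded task data: ternary design matrix X and sign outcomes y.

    ``mode`` is ``"paired_comparison"`` when each row is a signed difference
    between two objects, or ``"classification"`` when rows are single coded
    objects with binary labels.
    """

    X: np.ndarray
    y: np.ndarray
    mode: Literal["paired_comparison", "classification"]
    n_dropped_pairs: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be n x m and y length n")
        if self.y.size == 0:
            raise ValueError("empty dataset")
        if not np.isin(self.X, (-1.0, 0.0, 1.0)).all():
            raise ValueError("X entries must lie in {-1, 0, +1}")
        if not np.isin(self.y, (-1.0, 1.0)).all():
            raise ValueError("y entries must lie in {-1, +1}")
        if self.mode not in ("paired_comparison", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def y01(self) -> np.ndarray:
        """Outcomes remapped to {0, 1} for logistic likelihoods."""
        return (self.y > 0).astype(float)

    def subset(self, idx: np.ndarray) -> "DecisionDataset":
        return DecisionDataset(self.X[idx], self.y[idx], self.mode)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"x{j}" for j in range(self.m)])
        df["y"] = self.y
        return df


@dataclass(frozen=True)
class SplitSpec:
    """A seeded train/test partition request: n_train rows, one iteration."""

    n_train: int
    seed: int
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")


def read_raw_csv(path: str | Path, criterion: str) -> RawDataset:
    """Read a CSV with a named criterion column; listwise-delete missing rows."""
    df = pd.read_csv(path)
    if criterion not in df.columns:
        raise ValueError(f"criterion column {criterion!r} not found in {path}")
    n0 = len(df)
    df = df.dropna()
    names = [c for c in df.columns if c != criterion]
    return RawDataset(
        criterion=df[criterion].to_numpy(float),
        attributes=df[names].to_numpy(float),
        names=names,
        n_dropped=n0 - len(df),
    )


def median_split(raw: RawDataset, scheme: Literal["binary", "ternary"] = "binary") -> np.ndarray:
    """Code each attribute column relative to its median.

    binary  : 1 iff strictly above the column median, else 0.
    ternary : +1 above the median, 0 at the median, -1 below.

    A constant column codes to all zeros and triggers a warning.
    """
    if scheme not in ("binary", "ternary"):
        raise ValueError(f"unknown scheme {scheme!r}")
    A = raw.attributes
    med = np.median(A, axis=0)
    for j in range(raw.n_cues):
        if np.all(A[:, j] == A[0, j]):
            warnings.warn(f"attribute column {raw.names[j]!r} is constant; coded to all 0")
    if scheme == "binary":
        return (A > med).astype(float)
    return np.sign(A - med)


def make_paired_comparisons(
    coded: np.ndarray,
    criterion: np.ndarray,
    seed: int | None = 0,
) -> DecisionDataset:
    """Encode all object pairs as signed attribute differences.

    Each unordered pair {a, b} with unequal criterion values yields one row
    x = coded[right] - coded[left] and y = +1 iff criterion[right] >
    criterion[left]. The left/right orientation of each pair is randomized
    (seeded) so the outcome classes are balanced in expectation. Pairs tied
    on the criterion are dropped and counted in ``n_dropped_pairs``.
    """
    coded = np.asarray(coded, dtype=float)
    criterion = np.asarray(criterion, dtype=float)
    if not np.isin(coded, (0.0, 1.0)).all():
        raise ValueError("coded matrix must be binary {0,1}")
    N = coded.shape[0]
    if N < 2:
        raise ValueError("need at least 2 objects to form pairs")
    rng = np.random.default_rng(seed)
    ia, ib = np.triu_indices(N, k=1)
    keep = criterion[ia] != criterion[ib]
    n_dropped = int((~keep).sum())
    ia, ib = ia[keep], ib[keep]
    if ia.size == 0:
        raise ValueError("all pairs tied on the criterion; nothing to compare")
    # seeded orientation flip: left/right assignment per pair
    flip = rng.random(ia.size) < 0.5
    left = np.where(flip, ib, ia)
    right = np.where(flip, ia, ib)
    X = coded[right] - coded[left]
    y = np.where(criterion[right] > criterion[left], 1.0, -1.0)
    return DecisionDataset(X, y, "paired_comparison", n_dropped_pairs=n_dropped)


def make_classification(coded: np.ndarray, labels: Sequence[float]) -> DecisionDataset:
    """Wrap a ternary-coded object matrix and binary labels as a dataset.

    Labels given as {0, 1} are remapped to {-1, +1}.
    """
    coded = np.asarray(coded, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if coded.shape[0] != labels.shape[0]:
        raise ValueError("coded rows and labels length differ")
    if np.isin(labels, (0.0, 1.0)).all() and not np.isin(labels, (-1.0, 1.0)).all():
        labels = 2.0 * labels - 1.0
    return DecisionDataset(coded, labels, "classification")


_PROFILES = ("compensatory", "noncompensatory", "mixed")


def generate_synthetic_task(
    m: int,
    N: int,
    validity_profile: Literal["compensatory", "noncompensatory", "mixed"] = "compensatory",
    noise_sd: float = 0.5,
    seed: int | None = 0,
) -> RawDataset:
    """Generate a synthetic multi-attribute decision task.

    Attributes are i.i.d. standard normal; the criterion is a linear
    combination plus Gaussian noise. The validity profile fixes the spread of
    |beta|: ``compensatory`` uses equal magnitudes, ``noncompensatory`` a
    geometric ladder |beta_j| ~ 2^j (one dominant cue), ``mixed`` random
    log-spaced magnitudes. Coefficient signs are random (seeded).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if N < 10:
        raise ValueError("N must be >= 10")
    if validity_profile not in _PROFILES:
        raise ValueError(f"validity_profile must be one of {_PROFILES}")
    rng = np.random.default_rng(seed)
    if validity_profile == "compensatory":
        mag = np.ones(m)
    elif validity_profile == "noncompensatory":
        mag = 2.0 ** np.arange(m)
    else:
        mag = 2.0 ** rng.uniform(0.0, m - 1, size=m)
    beta = mag * rng.choice([-1.0, 1.0], size=m)
    A = rng.standard_normal((N, m))
    crit = A @ beta + noise_sd * rng.standard_normal(N)
    return RawDataset(criterion=crit, attributes=A)


def split_train_test(
    data: DecisionDataset, spec: SplitSpec
) -> tuple[DecisionDataset, DecisionDataset]:
    """Partition rows into a train set of spec.n_train rows and its complement.

    The split is seeded by (seed, iteration) so Monte-Carlo sweeps are
    reproducible and iterations are independent.
    """
    if spec.n_train >= data.n:
        raise ValueError(f"n_train={spec.n_train} must be < n={data.n}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, spec.iteration)))
    perm = rng.permutation(data.n)
    return data.subset(np.sort(perm[: spec.n_train])), data.subset(np.sort(perm[spec.n_train :]))


def write_dataset(data: DecisionDataset, path: str | Path, meta: dict | None = None) -> None:
    """Write a coded dataset as CSV plus a JSON sidecar with provenance."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    sidecar = {"mode": data.mode, "n": data.n, "m": data.m,
               "n_dropped_pairs": data.n_dropped_pairs, **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dataset(path: str | Path) -> DecisionDataset:
    """Read a coded dataset written by :func:`write_dataset`."""
    path = Path(path)
    df = pd.read_csv(path)
    mode = "paired_comparison"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        mode = json.loads(sidecar.read_text()).get("mode", mode)
    y = df.pop("y").to_numpy(float)
    return DecisionDataset(df.to_numpy(float), y, mode)
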