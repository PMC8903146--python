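"""Synthetic event-related BOLD simulation and beta-series estimation.

A run presents ``n_trials`` stimuli (boxcars of duration ED, one per trial,
separated by ISI, with ceil(n_trials/3) randomly interspersed null epochs)
convolved with a canonical double-gamma HRF and sampled every TR seconds.
Ground-truth per-trial weights for a d x d x d cluster of task-sensitive
voxels are drawn with Wishart-correlated spatial structure, embedded in a
3d x 3d x 3d "brain", and observed through

    Y = X_LSA @ Omega + E,

where E is i.i.d. scanner noise smoothed with a separable spatiotemporal
Gaussian kernel. Trial weights are then estimated three ways:

* LSA (least squares all)      — one GLM, one regressor per trial;
* LSS (least squares separate) — one 2-regressor GLM per trial (target
  trial + a shared nuisance regressor for all other trials);
* LSS-prior                    — ridge regression on the LSA design shrinking
  toward the LSS estimates, interpolating LSA (theta=0) to LSS (theta->inf).

Estimators are scored by per-voxel RMSE of the trial weights against the
ground truth, averaged over the cluster voxels and simulation iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist
from scipy.stats import wishart

__all__ = [
    "TrialSchedule",
    "NoiseParams",
    "GroundTruth",
    "BoldData",
    "double_gamma_hrf",
    "build_lsa_design",
    "build_lss_designs",
    "simulate_ground_truth",
    "simulate_bold",
    "fit_lsa",
    "fit_lss",
    "fit_lss_prior",
    "lss_prior_path",
    "rmse_score",
    "run_simulation_study",
]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class TrialSchedule:
    """Timing of one run: trial counts, TR/ED/ISI, null epochs, scan count."""

    n_trials: int = 40
    n_stimuli: int = 2
    TR: float = 1.0
    ED: float = 1.5
    ISI: float = 3.0
    t_end: float = 20.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.n_trials % self.n_stimuli:
            raise ValueError("n_trials must be divisible by n_stimuli")
        if min(self.TR, self.ED) <= 0 or self.ISI < 0:
            raise ValueError("TR, ED must be positive and ISI non-negative")

    @property
    def trial_duration(self) -> float:
        return self.ED + self.ISI

    @property
    def n_nulls(self) -> int:
        return math.ceil(self.n_trials / 3)

    @property
    def n_slots(self) -> int:
        return self.n_trials + self.n_nulls

    @property
    def n_scans(self) -> int:
        return math.ceil(((4.0 / 3.0) * self.n_trials * self.trial_duration + self.t_end) / self.TR)


@dataclass(frozen=True)
class NoiseParams:
    """Scanner-noise level and the spatiotemporal smoothing kernel.

    ``kernel_radius`` is the smoothing kernel's half-width in samples per
    axis. The default of 1 (a 3-tap kernel per axis, the compact kernel of
    the MATLAB volume-smoothing convention) deliberately truncates the
    Gaussian: it induces the intended spatiotemporal correlations while
    retaining noise power at trial frequency, which is what penalizes
    collinear single-trial designs. ``None`` uses the full kernel
    (truncated at 4 sigma), which leaves almost no high-frequency noise.
    """

    sigma_scanner2: float = 10000.0
    fwhm_mm: float = 4.0
    fwhm_s: float = 4.5
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.75)
    kernel_radius: int | None = 1


@dataclass
class GroundTruth:
    """Per-trial weights for the signal cluster and the embedding brain."""

    psi: np.ndarray       # (n_trials, d, d, d)
    omega: np.ndarray     # (n_trials, 3d, 3d, 3d)
    corner: tuple[int, int, int]
    mu: np.ndarray        # (n_stimuli, d**3)
    sigma: np.ndarray     # (d**3, d**3)
    conditions: np.ndarray  # (n_trials,) stimulus index per trial, in onset order

    @property
    def d(self) -> int:
        return self.psi.shape[1]

    def cluster_slices(self) -> tuple[slice, slice, slice]:
        cx, cy, cz = self.corner
        d = self.d
        return slice(cx, cx + d), slice(cy, cy + d), slice(cz, cz + d)


@dataclass
class BoldData:
    """Observed 4-D signal with the design and noise settings that made it."""

    Y: np.ndarray         # (n_scans, 3d, 3d, 3d)
    X_lsa: np.ndarray     # (n_scans, n_trials)
    noise: NoiseParams
    schedule: TrialSchedule

    def cluster_timeseries(self, truth: GroundTruth) -> np.ndarray:
        """Time-by-voxel matrix for the signal cluster, columns C-ordered."""
        sx, sy, sz = truth.cluster_slices()
        d = truth.d
        return self.Y[:, sx, sy, sz].reshape(self.Y.shape[0], d**3)


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times t (s), peak-normalized."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp) - ratio * gamma_dist.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def build_lsa_design(
    schedule: TrialSchedule,
    seed: int | np.random.Generator | None = 0,
    hrf_params: dict | None = None,
    oversample: int = 20,
    return_onsets: bool = False,
):
    """One HRF-convolved boxcar regressor per trial.

    Trials and null epochs occupy consecutive slots of duration ED + ISI;
    which slots are null is drawn at random (seeded). Each trial's regressor
    is a boxcar of duration ED at its onset, convolved with the double-gamma
    HRF on an oversampled grid and sampled at the scan times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_scans
    dt = schedule.TR / oversample
    last_needed = (schedule.n_slots - 1) * schedule.trial_duration + schedule.ED
    if last_needed > n * schedule.TR:
        raise ValueError("scan window too small for the trial schedule")
    null_slots = set(rng.choice(schedule.n_slots, size=schedule.n_nulls, replace=False).tolist())
    onsets = np.array(
        [s * schedule.trial_duration for s in range(schedule.n_slots) if s not in null_slots]
    )
    grid_len = int(round(n * schedule.TR / dt))
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt), **(hrf_params or {}))
    X = np.empty((n, schedule.n_trials))
    scan_idx = (np.arange(n) * oversample).astype(int)
    ed_len = max(1, int(round(schedule.ED / dt)))
    for k, onset in enumerate(onsets):
        box = np.zeros(grid_len)
        i0 = int(round(onset / dt))
        box[i0 : i0 + ed_len] = 1.0
        # discrete approximation of the continuous boxcar*HRF convolution
        X[:, k] = np.convolve(box, hrf)[:grid_len][scan_idx] * dt
    return (X, onsets) if return_onsets else X


def build_lss_designs(X_lsa: np.ndarray) -> list[np.ndarray]:
    """For each trial k: the n x 2 design [trial k, sum of all other trials]."""
    X_lsa = np.asarray(X_lsa, dtype=float)
    ell = X_lsa.shape[1]
    if ell < 2:
        raise ValueError("LSS needs at least 2 trials")
    total = X_lsa.sum(axis=1)
    return [np.column_stack([X_lsa[:, k], total - X_lsa[:, k]]) for k in range(ell)]


def sample_condition_params(
    d: int,
    n_stimuli: int,
    sigma_psi2: float,
    rng: np.random.Generator,
    off_diag: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus mean vectors and the Wishart-drawn voxel covariance.

    mu entries are i.i.d. N(0, sigma_psi2); Sigma ~ W(V, d^3)/d^3 with V
    having unit diagonal and ``off_diag`` everywhere else. These are the
    quantities held constant across the runs of one simulation iteration.
    """
    v = d**3
    mu = rng.standard_normal((n_stimuli, v)) * math.sqrt(sigma_psi2)
    V = np.full((v, v), off_diag)
    np.fill_diagonal(V, 1.0)
    sigma = wishart(df=v, scale=V / v).rvs(random_state=rng)
    if np.linalg.eigvalsh(sigma)[0] <= 0:  # numerical guard; a.s. PD for df >= dim
        sigma = sigma + 1e-8 * np.eye(v)
    return mu, sigma


def simulate_ground_truth(
    d: int = 7,
    n_trials: int = 40,
    n_stimuli: int = 2,
    sigma_psi2: float = 15.0,
    seed: int | np.random.Generator | None = 0,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    corner: tuple[int, int, int] | None = None,
) -> GroundTruth:
    """Draw one run's ground-truth weights and embed them in the brain array.

    Per-trial weight rows are N(mu_condition, Sigma) draws, stacked across
    conditions and randomly permuted along the trial axis; the permuted
    order defines each trial's condition label. The d-cube cluster is placed
    at a corner drawn uniformly so it fits inside the 3d-cube brain (pass
    ``mu``/``sigma``/``corner`` to hold them fixed across runs).
    """
    if n_trials % n_stimuli:
        raise ValueError("n_trials must be divisible by n_stimuli")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = d**3
    if mu is None or sigma is None:
        mu, sigma = sample_condition_params(d, n_stimuli, sigma_psi2, rng)
    L = np.linalg.cholesky(sigma)
    per = n_trials // n_stimuli
    M = np.vstack([mu[c] + rng.standard_normal((per, v)) @ L.T for c in range(n_stimuli)])
    labels = np.repeat(np.arange(n_stimuli), per)
    perm = rng.permutation(n_trials)
    M, labels = M[perm], labels[perm]
    psi = M.reshape(n_trials, d, d, d)
    if corner is None:
        hi = 3 * d - 2 * d  # inclusive upper corner index so the cluster fits
        corner = tuple(int(c) for c in rng.integers(0, hi + 1, size=3))
    omega = np.zeros((n_trials, 3 * d, 3 * d, 3 * d))
    cx, cy, cz = corner
    omega[:, cx : cx + d, cy : cy + d, cz : cz + d] = psi
    return GroundTruth(psi, omega, corner, mu, sigma, labels)


def smoothing_sigmas(noise: NoiseParams, TR: float) -> tuple[float, float, float, float]:
    """FWHM -> Gaussian sigma, per axis, in scan/voxel units."""
    st = noise.fwhm_s / (FWHM_TO_SIGMA * TR)
    sx, sy, sz = (noise.fwhm_mm / (FWHM_TO_SIGMA * v) for v in noise.voxel_mm)
    return st, sx, sy, sz


def simulate_bold(
    truth: GroundTruth,
    X_lsa: np.ndarray,
    noise: NoiseParams = NoiseParams(),
    schedule: TrialSchedule | None = None,
    seed: int | np.random.Generator | None = 0,
) -> BoldData:
    """Observed signal Y = X_LSA @ Omega + smoothed scanner noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X_lsa = np.asarray(X_lsa, dtype=float)
    n = X_lsa.shape[0]
    ell = X_lsa.shape[1]
    if ell != truth.omega.shape[0]:
        raise ValueError("design trials and ground-truth trials differ")
    schedule = schedule or TrialSchedule(n_trials=ell)
    vol = truth.omega.shape[1:]
    signal = (X_lsa @ truth.omega.reshape(ell, -1)).reshape((n,) + vol)
    if noise.sigma_scanner2 > 0:
        E = rng.standard_normal((n,) + vol) * math.sqrt(noise.sigma_scanner2)
        st, sx, sy, sz = smoothing_sigmas(noise, schedule.TR)
        kw = ({"radius": noise.kernel_radius} if noise.kernel_radius is not None
              else {"truncate": 4.0})
        E = gaussian_filter(E, sigma=(st, sx, sy, sz), mode="reflect", **kw)
        Y = signal + E
    else:
        Y = signal
    return BoldData(Y, X_lsa, noise, schedule)


def fit_lsa(X_lsa: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS trial weights; y may be one voxel (n,) or many (n, V)."""
    w, *_ = np.linalg.lstsq(np.asarray(X_lsa, float), np.asarray(y, float), rcond=None)
    return w


def fit_lss(designs: list[np.ndarray] | np.ndarray, y: np.ndarray) -> np.ndarray:
    """LSS trial weights: the target-trial coefficient of each 2-column GLM.

    Accepts either the list of per-trial designs or the LSA design (from
    which they are built). Returns (n_trials,) or (n_trials, V).
    """
    if isinstance(designs, np.ndarray):
        designs = build_lss_designs(designs)
    y = np.asarray(y, dtype=float)
    out = []
    for A in designs:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        out.append(coef[0])
    return np.stack(out)


def lss_prior_path(
    X_lsa: np.ndarray,
    Y: np.ndarray,
    thetas: np.ndarray,
    W_prior: np.ndarray,
) -> np.ndarray:
    """Ridge-toward-prior weights for every theta and voxel at once.

    Y is (n, V) and W_prior (n_trials, V); returns (n_thetas, n_trials, V).
    A single eigendecomposition of X'X serves the whole penalty grid.
    """
    X = np.asarray(X_lsa, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    W_prior = np.asarray(W_prior, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if np.any(thetas < 0):
        raise ValueError("theta must be >= 0")
    lam, V = np.linalg.eigh(X.T @ X)
    BX = V.T @ (X.T @ Y)          # (ell, V)
    BP = V.T @ W_prior
    out = np.empty((thetas.size, X.shape[1], Y.shape[1]))
    for i, th in enumerate(thetas):
        if np.isinf(th):
            out[i] = W_prior  # exact shrinkage limit: the LSS estimates
        elif th == 0.0 and lam[0] < 1e-10 * lam[-1]:
            out[i] = fit_lsa(X, Y)  # minimum-norm fallback when X'X is singular
        else:
            out[i] = V @ ((BX + th * BP) / (lam + th)[:, None])
    return out


def fit_lss_prior(X_lsa: np.ndarray, y: np.ndarray, theta: float, w_lss: np.ndarray):
    """Single-theta ridge on the LSA design shrinking toward the LSS weights.

    For a single voxel (1-D y) returns a :class:`~robustpriors.penalized.PenalizedFit`;
    for a time-by-voxel matrix returns the (n_trials, V) weight array.
    """
    from .penalized import ridge_fit
    from .priors import PriorSpec

    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return ridge_fit(X_lsa, y, theta, PriorSpec(np.asarray(w_lss, float), family="custom"))
    return lss_prior_path(X_lsa, y, np.array([float(theta)]), np.asarray(w_lss))[0]


def rmse_score(w_hat: np.ndarray, psi: np.ndarray) -> np.ndarray | float:
    """Per-voxel RMSE over trials: sqrt(mean_j (w_hat_j - psi_j)^2).

    Inputs of shape (n_trials,) give a scalar; (n_trials, V) a length-V
    vector (one RMSE per voxel).
    """
    w_hat = np.asarray(w_hat, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if w_hat.shape != psi.shape:
        raise ValueError("shape mismatch between estimates and ground truth")
    err = np.sqrt(np.mean((w_hat - psi) ** 2, axis=0))
    return float(err) if err.ndim == 0 else err


def _simulate_run(schedule, d, sigma_psi2, noise, mu, sigma, rng):
    X = build_lsa_design(schedule, seed=rng)
    truth = simulate_ground_truth(
        d=d, n_trials=schedule.n_trials, n_stimuli=schedule.n_stimuli,
        sigma_psi2=sigma_psi2, seed=rng, mu=mu, sigma=sigma,
    )
    bold = simulate_bold(truth, X, noise, schedule, seed=rng)
    return X, truth, bold


def run_simulation_study(
    isi_levels=(2.0, 3.0, 4.0),
    snr_levels=(10.0, 15.0, 20.0),
    theta_grid: np.ndarray | None = None,
    n_iterations: int = 25,
    runs: int = 2,
    seed: int = 0,
    n_trials: int = 40,
    n_stimuli: int = 2,
    d: int = 7,
    noise: NoiseParams = NoiseParams(),
) -> pd.DataFrame:
    """RMSE of LSA, LSS, and the LSS-prior continuum over the ISI x SNR grid.

    For each design cell and iteration: draw the condition means and voxel
    covariance once, simulate ``runs`` independent runs (independent designs,
    trial draws, cluster placement, and noise), estimate each run's cluster
    voxels with every model, score against that run's ground truth, and
    average over runs and cluster voxels. Returns a tidy frame with one row
    per (ISI, sigma_psi2, model, theta, iteration); theta is NaN for the
    un-penalized LSA and LSS rows.
    """
    theta_grid = (
        np.logspace(-2, 5, 10) if theta_grid is None else np.asarray(theta_grid, float)
    )
    rows = []
    root = np.random.SeedSequence(seed)
    for isi in isi_levels:
        schedule = TrialSchedule(n_trials=n_trials, n_stimuli=n_stimuli, ISI=float(isi))
        for sigma_psi2 in snr_levels:
            cell_ss = np.random.SeedSequence(
                (seed, int(round(isi * 10)), int(round(sigma_psi2 * 10)))
            )
            for it, it_ss in enumerate(cell_ss.spawn(n_iterations)):
                rng = np.random.default_rng(it_ss)
                mu, sigma = sample_condition_params(d, n_stimuli, sigma_psi2, rng)
                acc: dict[tuple, list[float]] = {}
                for _ in range(runs):
                    X, truth, bold = _simulate_run(
                        schedule, d, sigma_psi2, noise, mu, sigma, rng
                    )
                    Yc = bold.cluster_timeseries(truth)
                    psi = truth.psi.reshape(n_trials, -1)
                    w_lsa = fit_lsa(X, Yc)
                    w_lss = fit_lss(X, Yc)
                    acc.setdefault(("lsa", float("nan")), []).append(
                        float(np.mean(rmse_score(w_lsa, psi)))
                    )
                    acc.setdefault(("lss", float("nan")), []).append(
                        float(np.mean(rmse_score(w_lss, psi)))
                    )
                    W = lss_prior_path(X, Yc, theta_grid, w_lss)
                    for th, w in zip(theta_grid, W):
                        acc.setdefault(("lss_prior", float(th)), []).append(
                            float(np.mean(rmse_score(w, psi)))
                        )
                for (model, th), vals in acc.items():
                    rows.append(
                        {"isi": float(isi), "sigma_psi2": float(sigma_psi2),
                         "model": model, "theta": th, "iteration": it,
                         "rmse": float(np.mean(vals))}
                    )
    _ = root
    return pd.DataFrame(rows)


def export_nifti(bold: BoldData, path) -> None:
    """Write one simulated 4-D volume as NIfTI (requires nibabel)."""
    import nibabel as nib

    vx = bold.noise.voxel_mm
    affine = np.diag([vx[0], vx[1], vx[2], 1.0])
    # NIfTI stores x,y,z,t; our array is t,x,y,z
    img = nib.Nifti1Image(np.moveaxis(bold.Y, 0, -1), affine)
    img.header.set_zooms((vx[0], vx[1], vx[2], bold.schedule.TR))
    nib.save(img, str(path))
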