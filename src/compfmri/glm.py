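"""First-level GLM for block-design BOLD time series.

The participant-level model mirrors the standard mass-univariate approach
for blocked task fMRI:

* condition regressors are 30-s boxcars convolved with the canonical
  double-gamma haemodynamic response function (HRF), built at a microtime
  resolution of 16 bins per TR and sampled at mid-TR;
* six rigid-body motion parameters may be appended as nuisance regressors;
* a discrete cosine set high-pass filters model and data at 1/128 Hz;
* the error is modelled as AR(1)-plus-white noise whose hyperparameters are
  estimated by restricted maximum likelihood (ReML) pooled over
  task-responsive voxels, and the estimated covariance is used to prewhiten
  model and data before ordinary least squares;
* the quantity carried forward to the group level is the per-voxel
  Hard - Easy contrast of parameter estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import toeplitz
from scipy.stats import gamma as _gamma

from .core import StatMap, VoxelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDesign",
    "DesignMatrix",
    "GLMResult",
    "canonical_hrf",
    "dct_basis",
    "build_design",
    "grand_mean_scale",
    "fit_prewhitened_glm",
    "contrast_image",
]

HIGHPASS_CUTOFF_S = 128.0
MICROTIME_BINS = 16
HRF_DURATION_S = 32.0


@dataclass
class BlockDesign:
    """Block onsets/durations/labels for one run.

    Conditions are free-form strings; the compensation analysis uses
    ``"easy"`` and ``"hard"``.
    """

    onsets: np.ndarray
    durations: np.ndarray
    labels: list[str]
    tr: float
    n_scans: int

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.labels)):
            raise ValueError("onsets, durations and labels must align")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be sorted ascending")
        total = self.n_scans * self.tr
        if np.any(self.onsets + self.durations > total + 1e-9):
            raise ValueError(
                f"blocks extend past the run: last block ends at "
                f"{np.max(self.onsets + self.durations):g} s but the run is "
                f"{total:g} s"
            )

    @property
    def conditions(self) -> list[str]:
        """Unique condition labels in stable (sorted) order."""
        return sorted(set(self.labels))

    def to_events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(onset=self.onsets, duration=self.durations,
                 trial_type=self.labels)
        )


@dataclass
class DesignMatrix:
    """Condition + nuisance regressors plus the high-pass cosine basis.

    ``values`` holds the HRF-convolved condition columns followed by any
    motion covariates; the orthonormal cosine basis (which includes the
    constant) is kept separately in ``high_pass_basis`` and always enters
    the model.
    """

    values: np.ndarray
    names: list[str]
    high_pass_basis: np.ndarray
    condition_names: list[str]
    tr: float
    contrast_vectors: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def contrast_weights(self, contrast: str | dict[str, float]) -> np.ndarray:
        """Expand a named or dict-form contrast into a weight vector over
        ``names``.  Unknown regressor names raise ``KeyError``."""
        if isinstance(contrast, str):
            try:
                contrast = self.contrast_vectors[contrast]
            except KeyError:
                raise KeyError(f"unknown contrast {contrast!r}") from None
        w = np.zeros(len(self.names))
        for name, weight in contrast.items():
            if name not in self.names:
                raise KeyError(f"unknown regressor {name!r}")
            w[self.names.index(name)] = weight
        return w


@dataclass
class GLMResult:
    """Per-voxel estimates from the prewhitened first-level fit."""

    betas: np.ndarray  # (n_voxels, n_regressors)
    names: list[str]
    contrast: np.ndarray  # (n_voxels,) Hard - Easy
    residual_variance: np.ndarray  # (n_voxels,)
    ar1: float  # pooled lag-1 error autocorrelation
    scaling: float  # grand-mean factor applied upstream (1.0 if none)
    dof: float
    whitener: np.ndarray | None = None  # (n_scans, n_scans), reused by MVB
    n_highpass: int = 0
    # AR(1)-plus-white hyperparameters (white variance, AR variance, AR coef)
    ar_params: tuple[float, float, float] = (1.0, 0.0, 0.0)


def canonical_hrf(
    dt: float,
    duration: float = HRF_DURATION_S,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``[0, duration]`` at
    spacing ``dt``.

    The kernel is the difference of two gamma densities: a response peaking
    near 5 s and a later undershoot scaled by ``undershoot_ratio``.  It is
    normalised to unit sum so convolution preserves block amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    peak = _gamma.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = _gamma.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - undershoot_ratio * under
    return h / h.sum()


def dct_basis(n_scans: int, tr: float, cutoff: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Orthonormal discrete cosine basis implementing a high-pass filter.

    The number of regressors (including the constant) is
    ``K = floor(2 * T / cutoff + 1)`` for run length ``T`` seconds, so that
    retained drifts are those slower than ``1 / cutoff`` Hz.
    """
    total = n_scans * tr
    k = int(2.0 * total / cutoff + 1.0)
    k = max(k, 1)
    n = np.arange(n_scans)
    basis = np.empty((n_scans, k))
    basis[:, 0] = 1.0 / np.sqrt(n_scans)
    for j in range(1, k):
        basis[:, j] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * (2 * n + 1) * j / (2 * n_scans)
        )
    return basis


def _convolved_conditions(block_design: BlockDesign,
                          microtime: int = MICROTIME_BINS) -> np.ndarray:
    """HRF-convolved boxcar for each condition, sampled at mid-TR."""
    tr = block_design.tr
    dt = tr / microtime
    n_hr = block_design.n_scans * microtime
    hrf = canonical_hrf(dt)
    cols = []
    for cond in block_design.conditions:
        boxcar = np.zeros(n_hr)
        for onset, dur, lab in zip(
            block_design.onsets, block_design.durations, block_design.labels
        ):
            if lab != cond:
                continue
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            boxcar[i0:i1] = 1.0
        conv = np.convolve(boxcar, hrf)[:n_hr]
        sample = np.arange(block_design.n_scans) * microtime + microtime // 2
        cols.append(conv[sample])
    return np.column_stack(cols)


def build_design(
    block_design: BlockDesign,
    motion: np.ndarray | None = None,
    microtime: int = MICROTIME_BINS,
    highpass_cutoff: float = HIGHPASS_CUTOFF_S,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Parameters
    ----------
    motion:
        Optional ``(n_scans, 6)`` rigid-body parameters appended as
        nuisance regressors.
    """
    cond_cols = _convolved_conditions(block_design, microtime=microtime)
    names = list(block_design.conditions)
    values = cond_cols
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != block_design.n_scans:
            raise ValueError(
                f"motion has {motion.shape[0]} rows, expected "
                f"{block_design.n_scans}"
            )
        values = np.column_stack([values, motion])
        names += [f"motion_{ax}" for ax in
                  ("tx", "ty", "tz", "rx", "ry", "rz")][: motion.shape[1]]
    basis = dct_basis(block_design.n_scans, block_design.tr, cutoff=highpass_cutoff)
    contrasts: dict[str, dict[str, float]] = {}
    if {"easy", "hard"} <= set(block_design.conditions):
        contrasts["hard_gt_easy"] = {"hard": 1.0, "easy": -1.0}
    return DesignMatrix(
        values=values,
        names=names,
        high_pass_basis=basis,
        condition_names=list(block_design.conditions),
        tr=block_design.tr,
        contrast_vectors=contrasts,
    )


def grand_mean_scale(data: VoxelDataset, target: float = 100.0) -> tuple[VoxelDataset, float]:
    """Scale a run so the mean over all voxels and scans equals ``target``.

    Returns the scaled dataset and the multiplicative factor applied.
    """
    mean = float(np.mean(data.data))
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("grand mean must be positive to scale")
    factor = target / mean
    scaled = VoxelDataset(
        data=data.data * factor,
        coords=data.coords,
        shape=data.shape,
        tr=data.tr,
        affine=data.affine,
    )
    return scaled, factor


# ---------------------------------------------------------------------------
# AR(1)-plus-white-noise ReML
# ---------------------------------------------------------------------------

def _ar1_corr(n: int, a: float) -> np.ndarray:
    return toeplitz(a ** np.arange(n))


def estimate_ar1_white_reml(
    residual_basis: np.ndarray,
    pooled: np.ndarray,
    max_ar: float = 0.95,
) -> tuple[float, float, float]:
    """ReML fit of ``sigma_w^2 I + sigma_a^2 AR1(a)`` to pooled residuals.

    Parameters
    ----------
    residual_basis:
        ``(n_scans, m)`` orthonormal basis of the residual-forming space
        (the orthogonal complement of design plus filter), so the fit is a
        restricted likelihood.
    pooled:
        ``(n_scans, V)`` data from the pooled voxels.

    Returns
    -------
    (sigma_w2, sigma_a2, a):
        White and AR variance components and the AR coefficient.
    """
    n = pooled.shape[0]
    nv = pooled.shape[1]
    m = residual_basis.shape[1]
    proj = residual_basis.T @ pooled  # (m, V)
    scatter = proj @ proj.T  # (m, m)
    total_var = np.trace(scatter) / (m * nv)
    if total_var < 1e-12:
        return total_var, 0.0, 0.0

    l0 = np.log(total_var / 2.0)

    def profile_at(a: float) -> tuple[float, float, float]:
        """Minimise over the two variances at fixed AR coefficient.

        In the eigenbasis of the projected AR correlation matrix the
        restricted covariance is diagonal, so each objective evaluation
        is O(m) and the 2D inner problem is cheap.
        """
        m_a = residual_basis.T @ _ar1_corr(n, a) @ residual_basis
        d, vecs = np.linalg.eigh(m_a)
        d = np.maximum(d, 0.0)
        diag_s = np.sum((scatter @ vecs) * vecs, axis=0)

        def nll(theta: np.ndarray):
            sw2 = np.exp(theta[0])
            sa2 = np.exp(theta[1])
            lam = sw2 + sa2 * d
            f = 0.5 * (nv * np.sum(np.log(lam)) + np.sum(diag_s / lam))
            common = nv / lam - diag_s / lam**2
            grad = 0.5 * np.array(
                [np.sum(common) * sw2, np.sum(common * d) * sa2]
            )
            return f, grad

        res = optimize.minimize(
            nll,
            x0=np.array([l0, l0]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(l0 - 20, l0 + 6), (l0 - 20, l0 + 6)],
        )
        return float(res.fun), float(np.exp(res.x[0])), float(np.exp(res.x[1]))

    # coarse grid over the AR coefficient, then one local refinement
    grid = np.arange(0.0, max_ar + 1e-9, 0.1)
    vals = [profile_at(a) for a in grid]
    i_best = int(np.argmin([v[0] for v in vals]))
    a_best, (f_best, sw2, sa2) = grid[i_best], vals[i_best]
    for a in np.clip(
        a_best + np.array([-0.06, -0.03, -0.015, 0.015, 0.03, 0.06]),
        0.0, max_ar,
    ):
        f, w, s = profile_at(float(a))
        if f < f_best:
            f_best, sw2, sa2, a_best = f, w, s, float(a)
    return sw2, sa2, float(a_best)


def _whitener_from_cov(cov: np.ndarray) -> np.ndarray:
    """Inverse matrix square root of a symmetric positive-definite matrix."""
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, 1e-12 * vals.max())
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def fit_prewhitened_glm(
    data: VoxelDataset,
    design: DesignMatrix,
    pool_min_voxels: int = 32,
    pool_alpha: float = 0.001,
    max_ar: float = 0.95,
) -> GLMResult:
    """Fit the prewhitened first-level GLM to every voxel.

    Procedure: (1) an initial OLS fit (with the cosine filter in the model)
    yields residuals; (2) an omnibus F statistic over the condition columns
    selects a task-responsive voxel pool (falling back to the most
    responsive ``pool_min_voxels`` voxels); (3) AR(1)-plus-white
    hyperparameters are estimated by ReML over the pool; (4) model and data
    are prewhitened by the inverse square root of the implied covariance
    and refit by OLS.
    """
    y = data.data
    x = np.column_stack([design.values, design.high_pass_basis])
    names = design.names + [f"cosine_{i}" for i in
                            range(design.high_pass_basis.shape[1])]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("design rows must equal number of scans")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify offending columns by comparing ranks without each column
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; redundant columns: {bad}"
        )

    beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid0 = y - x @ beta0
    dof0 = n - p
    rss = np.sum(resid0**2, axis=0)
    sigma2 = rss / dof0

    # omnibus F over condition columns
    n_cond = len(design.condition_names)
    x_red = x[:, n_cond:]
    beta_r, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    rss_r = np.sum((y - x_red @ beta_r) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ((rss_r - rss) / n_cond) / np.where(sigma2 > 0, sigma2, np.inf)
    from scipy.stats import f as f_dist

    f_crit = f_dist.isf(pool_alpha, n_cond, dof0)
    pool = np.nonzero(fstat > f_crit)[0]
    if pool.size < pool_min_voxels:
        pool = np.argsort(fstat)[::-1][: min(pool_min_voxels, y.shape[1])]

    # ReML in the residual-forming space of the full model
    u, s, _ = np.linalg.svd(x, full_matrices=True)
    resid_basis = u[:, rank:]
    sw2, sa2, a = estimate_ar1_white_reml(resid_basis, y[:, pool], max_ar=max_ar)
    denom = sw2 + sa2
    ar1 = float(sa2 * a / denom) if denom > 1e-12 else 0.0

    if denom > 1e-12:
        cov = sw2 * np.eye(n) + sa2 * _ar1_corr(n, a)
        cov /= denom  # whiten by the correlation shape; scale is irrelevant
        whitener = _whitener_from_cov(cov)
    else:
        whitener = np.eye(n)

    wx = whitener @ x
    wy = whitener @ y
    beta, *_ = np.linalg.lstsq(wx, wy, rcond=None)
    resid = wy - wx @ beta
    dof = n - rank
    res_var = np.sum(resid**2, axis=0) / dof

    betas = beta[: len(design.names)].T  # drop cosine betas, voxels first
    if {"easy", "hard"} <= set(design.condition_names):
        i_hard = design.names.index("hard")
        i_easy = design.names.index("easy")
        contrast = betas[:, i_hard] - betas[:, i_easy]
    else:
        contrast = np.zeros(y.shape[1])
    return GLMResult(
        betas=betas,
        names=list(design.names),
        contrast=contrast,
        residual_variance=res_var,
        ar1=ar1,
        scaling=1.0,
        dof=float(dof),
        whitener=whitener,
        n_highpass=design.high_pass_basis.shape[1],
        ar_params=(sw2, sa2, a),
    )


def whitener_from_ar_params(n_scans: int, ar_params: tuple[float, float, float]) -> np.ndarray:
    """Rebuild the prewhitening matrix from stored AR hyperparameters."""
    sw2, sa2, a = ar_params
    denom = sw2 + sa2
    if denom <= 1e-12:
        return np.eye(n_scans)
    cov = (sw2 * np.eye(n_scans) + sa2 * _ar1_corr(n_scans, a)) / denom
    return _whitener_from_cov(cov)


def contrast_image(
    glm: GLMResult,
    weights: dict[str, float],
    dataset: VoxelDataset,
) -> StatMap:
    """Weighted sum of betas written back onto the 3D grid.

    ``weights`` maps regressor names to contrast weights; names absent from
    the model raise ``KeyError``.
    """
    w = np.zeros(len(glm.names))
    for name, weight in weights.items():
        if name not in glm.names:
            raise KeyError(f"unknown regressor {name!r}")
        w[glm.names.index(name)] = weight
    values = glm.betas @ w
    return StatMap(
        values=dataset.map_from_values(values),
        kind="coefficient",
        df=glm.dof,
        affine=dataset.affine,
    )
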