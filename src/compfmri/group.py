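"""Group-level univariate analysis.

Cohort assembly (performance scoring and chance-level exclusion), the
behavioural age regression, voxel-wise multiple regression of the
Hard - Easy contrast on standardised age, performance, sex and their
interaction, threshold-free cluster enhancement (TFCE) with
permutation-based family-wise-error correction, definition of
"compensation candidate" ROIs as the connected intersection of the
positive age and performance effects, vascular (RSFA) scaling, and the
ROI-level multiple regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ParticipantRecord, ROIMask, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "score_and_exclude",
    "standardise_covariates",
    "behaviour_regression",
    "group_design",
    "group_voxelwise",
    "tfce_enhance",
    "permutation_inference",
    "intersection_roi",
    "rsfa_scale",
    "roi_regression",
    "one_sample_tmap",
]

TFCE_E = 0.5
TFCE_H = 2.0
T_THRESHOLD = 1.97
N_PERMUTATIONS = 2000
CONNECTIVITY_STRUCT = np.ones((3, 3, 3), dtype=bool)  # 26-neighbour


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    included: list[ParticipantRecord]
    excluded: list[ParticipantRecord]
    reasons: dict[str, str]


def score_and_exclude(
    records: list[ParticipantRecord],
    chance_proportion: float = 0.5,
) -> ExclusionReport:
    """Compute performance scores and drop at-chance participants.

    A participant is flagged as at-chance when their overall proportion of
    correct trials falls below ``chance_proportion``; participants with no
    recorded responses are excluded with reason ``"no responses"``.
    """
    included, excluded, reasons = [], [], {}
    for r in records:
        for name in ("hard_correct", "hard_incorrect", "easy_correct", "easy_incorrect"):
            if getattr(r, name) < 0:
                raise ValueError(f"negative count {name} for {r.id}")
        if r.n_trials == 0:
            excluded.append(r)
            reasons[r.id] = "no responses"
        elif r.proportion_correct < chance_proportion:
            excluded.append(r)
            reasons[r.id] = (
                f"at chance (proportion correct "
                f"{r.proportion_correct:.2f} < {chance_proportion:g})"
            )
        else:
            included.append(r)
    if not included:
        raise ValueError("all participants excluded")
    for pid, why in reasons.items():
        logger.info("excluded %s: %s", pid, why)
    return ExclusionReport(included=included, excluded=excluded, reasons=reasons)


def standardise_covariates(records: list[ParticipantRecord]) -> None:
    """Z-score age and performance over the (post-exclusion) cohort."""
    from .simulate import standardise_records

    standardise_records(records)


def _sex_numeric(records: list[ParticipantRecord]) -> np.ndarray:
    """Standardised numeric sex covariate (z-scored 0/1 coding)."""
    raw = np.array([1.0 if r.sex == "M" else 0.0 for r in records])
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()


def behaviour_regression(
    records: list[ParticipantRecord],
    standardise_outcome: bool = True,
) -> pd.DataFrame:
    """OLS of performance on standardised age with a sex covariate.

    Returns a tidy coefficient table (term, estimate, t, p) with the model
    R^2 and residual degrees of freedom attached as ``DataFrame.attrs``.
    """
    import statsmodels.api as sm

    if len(records) < 3:
        raise ValueError("need at least 3 records")
    if any(r.z_age is None for r in records):
        standardise_covariates(records)
    y = np.array([r.performance for r in records], dtype=float)
    if standardise_outcome:
        if y.std() == 0:
            raise ValueError("performance is constant")
        y = (y - y.mean()) / y.std()
    x = np.column_stack(
        [np.array([r.z_age for r in records]), _sex_numeric(records)]
    )
    if np.any(np.std(x, axis=0) == 0):
        raise ValueError("constant predictor in behavioural model")
    x = sm.add_constant(x)
    fit = sm.OLS(y, x).fit()
    table = pd.DataFrame(
        dict(
            term=["const", "age", "sex"],
            estimate=fit.params,
            t=fit.tvalues,
            p=fit.pvalues,
        )
    )
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["df_resid"] = float(fit.df_resid)
    return table


# ---------------------------------------------------------------------------
# voxel-wise group model
# ---------------------------------------------------------------------------

GROUP_TERMS = ["const", "age", "performance", "sex", "age_x_performance"]


def group_design(records: list[ParticipantRecord]) -> np.ndarray:
    """Design matrix [1, z_age, z_perf, z_sex, z_age*z_perf]."""
    if any(r.z_age is None or r.z_performance is None for r in records):
        standardise_covariates(records)
    z_age = np.array([r.z_age for r in records])
    z_perf = np.array([r.z_performance for r in records])
    sex = _sex_numeric(records)
    x = np.column_stack(
        [np.ones(len(records)), z_age, z_perf, sex, z_age * z_perf]
    )
    corr = np.corrcoef(x[:, 1:].T)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    if np.any(np.abs(off) > 1 - 1e-10):
        raise np.linalg.LinAlgError("collinear group design")
    return x


def _fit_voxelwise(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorised OLS over voxels: returns betas, t values and residual dof."""
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y  # (p, V)
    resid = y - x @ beta
    dof = n - np.linalg.matrix_rank(x)
    sigma2 = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return beta, t, float(dof)


def _stack_maps(maps: list[StatMap]) -> tuple[np.ndarray, np.ndarray, tuple]:
    shape = maps[0].values.shape
    stack = np.stack([m.values for m in maps])  # (n, X, Y, Z)
    finite = np.all(np.isfinite(stack), axis=0)
    y = stack[:, finite]
    return y, finite, shape


def group_voxelwise(
    maps: list[StatMap],
    records: list[ParticipantRecord],
) -> dict[str, dict[str, StatMap]]:
    """Per-voxel multiple regression of contrast maps on the group design.

    Age and performance effects are estimated simultaneously, so each map
    reflects the unique contribution of its term.  Returns, per term, a
    coefficient map and a t map.
    """
    if len(maps) != len(records):
        raise ValueError("one contrast map per record required")
    x = group_design(records)
    y, finite, shape = _stack_maps(maps)
    beta, t, dof = _fit_voxelwise(x, y)
    out: dict[str, dict[str, StatMap]] = {}
    for j, term in enumerate(GROUP_TERMS):
        cmap = np.full(shape, np.nan)
        tmap = np.full(shape, np.nan)
        cmap[finite] = beta[j]
        tmap[finite] = t[j]
        out[term] = {
            "coefficient": StatMap(cmap, kind="coefficient", df=dof,
                                   affine=maps[0].affine),
            "t": StatMap(tmap, kind="t", df=dof, affine=maps[0].affine),
        }
    return out


def one_sample_tmap(maps: list[StatMap]) -> StatMap:
    """One-sample t map of the mean contrast (used to locate the
    task-positive network)."""
    y, finite, shape = _stack_maps(maps)
    n = y.shape[0]
    mean = y.mean(axis=0)
    se = y.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    tmap = np.full(shape, np.nan)
    tmap[finite] = t
    return StatMap(tmap, kind="t", df=n - 1, affine=maps[0].affine)


# ---------------------------------------------------------------------------
# TFCE + permutation inference
# ---------------------------------------------------------------------------

def tfce_enhance(
    stat_map: np.ndarray | StatMap,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float | None = None,
    n_steps: int = 100,
    structure: np.ndarray = CONNECTIVITY_STRUCT,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    Each voxel accumulates ``extent(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2dh, ...`` up to the map maximum, where ``extent(h)`` is the
    size of the voxel's connected suprathreshold cluster (26-connectivity
    by default).  ``dh`` defaults to ``max / n_steps``.
    """
    values = stat_map.values if isinstance(stat_map, StatMap) else np.asarray(stat_map)
    pos = np.where(np.isfinite(values), values, 0.0)
    pos = np.maximum(pos, 0.0)
    out = np.zeros_like(pos, dtype=float)
    vmax = pos.max()
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    n_thresh = int(np.floor(vmax / dh + 1e-9))
    for i in range(1, n_thresh + 1):
        h = i * dh
        supra = pos >= h - 1e-12
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(supra, sizes[labels] ** E * h**H * dh, 0.0)
    return out


@dataclass
class PermutationResult:
    term: str
    t_map: StatMap
    tfce_map: StatMap
    p_map: StatMap  # family-wise corrected
    sig_mask: np.ndarray
    max_null: np.ndarray
    n_perm: int


def permutation_inference(
    maps: list[StatMap],
    records: list[ParticipantRecord],
    term: str,
    n_perm: int = N_PERMUTATIONS,
    t_threshold: float = T_THRESHOLD,
    alpha: float = 0.05,
    tfce_kwargs: dict | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Family-wise corrected inference on one group term via max-TFCE.

    Uses Freedman-Lane permutation: data are residualised against the
    reduced model (all covariates except the tested term), residual rows
    are permuted, the reduced-model fit is added back, and the full-model
    t map of the tested term is TFCE-enhanced; the maximum over voxels
    forms the null distribution.  The significance mask is the conjunction
    of corrected ``p < alpha`` and ``t > t_threshold`` (positive effects).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if term not in GROUP_TERMS or term == "const":
        raise ValueError(f"cannot test term {term!r}")
    x = group_design(records)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("fewer participants than model terms")
    j = GROUP_TERMS.index(term)
    tfce_kwargs = dict(tfce_kwargs or {})

    y, finite, shape = _stack_maps(maps)
    _, t_obs, dof = _fit_voxelwise(x, y)
    t_full = np.full(shape, np.nan)
    t_full[finite] = t_obs[j]
    tfce_obs = tfce_enhance(t_full, **tfce_kwargs)

    z = np.delete(x, j, axis=1)
    pz = z @ np.linalg.pinv(z)
    fitted = pz @ y
    resid = y - fitted

    rng = np.random.default_rng(seed)
    n = y.shape[0]
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_b = fitted + resid[perm]
        _, t_b, _ = _fit_voxelwise(x, y_b)
        t_b_full = np.zeros(shape)
        t_b_full[finite] = t_b[j]
        max_null[b] = tfce_enhance(t_b_full, **tfce_kwargs).max()

    sorted_null = np.sort(max_null)
    exceed = n_perm - np.searchsorted(sorted_null, tfce_obs, side="left")
    p_corr = (1.0 + exceed) / (1.0 + n_perm)
    p_corr = np.where(finite, p_corr, np.nan)
    sig = finite & (p_corr < alpha) & (t_full > t_threshold)
    affine = maps[0].affine
    return PermutationResult(
        term=term,
        t_map=StatMap(t_full, kind="t", df=dof, affine=affine),
        tfce_map=StatMap(tfce_obs, kind="tfce", affine=affine),
        p_map=StatMap(p_corr, kind="p", affine=affine),
        sig_mask=sig,
        max_null=max_null,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# ROI definition and RSFA scaling
# ---------------------------------------------------------------------------

def intersection_roi(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    structure: np.ndarray = CONNECTIVITY_STRUCT,
    label_prefix: str = "roi",
    min_size: int = 1,
    affine: np.ndarray | None = None,
) -> list[ROIMask]:
    """Connected components of the AND of two significance masks.

    Components are ordered by size (largest first, ties by first voxel
    index) and labelled ``{prefix}_1``, ``{prefix}_2``, ...  An empty
    intersection returns an empty list with a warning.
    """
    both = np.asarray(sig_a, dtype=bool) & np.asarray(sig_b, dtype=bool)
    labels, n_lab = ndimage.label(both, structure=structure)
    if n_lab == 0:
        logger.warning("intersection of significance masks is empty")
        return []
    sizes = np.bincount(labels.ravel())
    order = sorted(
        range(1, n_lab + 1),
        key=lambda k: (-sizes[k], int(np.argmax(labels.ravel() == k))),
    )
    rois = []
    for rank, k in enumerate(order, start=1):
        if sizes[k] < min_size:
            continue
        kwargs = {} if affine is None else {"affine": affine}
        rois.append(ROIMask(mask=labels == k, label=f"{label_prefix}_{rank}",
                            **kwargs))
    return rois


def rsfa_scale(contrast: np.ndarray, rsfa: np.ndarray) -> np.ndarray:
    """Voxel-wise division of a contrast map by the RSFA map.

    Voxels with non-positive RSFA are set to NaN (and counted in the log)
    so they drop out of ROI means.
    """
    contrast = np.asarray(contrast, dtype=float)
    rsfa = np.asarray(rsfa, dtype=float)
    if contrast.shape != rsfa.shape:
        raise ValueError("maps must be aligned")
    bad = ~(rsfa > 0)
    if bad.any():
        logger.info("rsfa_scale: %d non-positive RSFA voxels excluded",
                    int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, contrast / rsfa)
    return out


def roi_mean_activation(
    roi: ROIMask,
    maps: list[StatMap],
    rsfa_maps: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-participant ROI-mean contrast, optionally RSFA-scaled first."""
    out = np.empty(len(maps))
    for i, m in enumerate(maps):
        vals = m.values
        if rsfa_maps is not None:
            vals = rsfa_scale(vals, rsfa_maps[i])
        sel = vals[roi.mask]
        out[i] = np.nanmean(sel)
    return out


def roi_regression(
    roi: ROIMask,
    maps: list[StatMap],
    records: list[ParticipantRecord],
    rsfa_maps: list[np.ndarray] | None = None,
    standardise_outcome: bool = False,
    n_comparisons: int = 2,
) -> pd.DataFrame:
    """ROI-mean activation regressed on age, performance, sex and the
    age x performance interaction.

    With ``standardise_outcome`` the coefficient column is on the
    standardised-activation scale (table-style reporting); without it the
    coefficients are in contrast units per SD of the covariate, which is
    the scale on which ground-truth slopes are specified.  The Bonferroni
    alpha for the ROI family is attached as ``attrs["alpha_bonferroni"]``.
    """
    import statsmodels.api as sm

    y = roi_mean_activation(roi, maps, rsfa_maps=rsfa_maps)
    if standardise_outcome:
        if y.std() == 0:
            raise ValueError("constant ROI activation")
        y = (y - y.mean()) / y.std()
    x = group_design(records)
    fit = sm.OLS(y, x).fit()
    table = pd.DataFrame(
        dict(
            term=GROUP_TERMS,
            estimate=fit.params,
            t=fit.tvalues,
            p=fit.pvalues,
        )
    )
    table.attrs["roi"] = roi.label
    table.attrs["n_voxels"] = roi.n_voxels
    table.attrs["alpha_bonferroni"] = 0.05 / n_comparisons
    table.attrs["df_resid"] = float(fit.df_resid)
    table.attrs["scaled"] = rsfa_maps is not None
    return table
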