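"""Compensation inference from MVB model comparisons.

A candidate region "compensates" if its multivoxel pattern carries task
information beyond that of the multiple demand network (MDN).  The test:
decode the Hard > Easy target from (a) a joint model containing the
candidate ROI plus an equally sized set of the most task-responsive MDN
voxels and (b) an MDN-only model; categorise the log-evidence difference
as a boost (> 3 nats, Bayes factor ~ 20), ambiguous ([-3, 3]) or a
reduction (< -3); then ask whether age increases the likelihood of a
boost, controlling for sex and the region's mean univariate response.
A second, more lenient index is the spread (standard deviation) of the
posterior decoding weights over the region's voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParticipantRecord, ROIMask, StatMap
from .mvb import MVBResult

logger = logging.getLogger(__name__)

__all__ = [
    "ModelComparison",
    "select_matched_mdn",
    "compare_models",
    "weight_spread",
    "build_group_table",
    "boost_model",
    "spread_model",
]

BOOST_NATS = 3.0


@dataclass
class ModelComparison:
    """Joint-versus-single model evidence comparison for one participant.

    ``category`` follows the +/-3-nat rule with the boundary assigned to
    "ambiguous": boost iff delta > 3, reduction iff delta < -3.
    """

    logev_joint: float
    logev_single: float

    @property
    def delta(self) -> float:
        return self.logev_joint - self.logev_single

    @property
    def category(self) -> str:
        if self.delta > BOOST_NATS:
            return "boost"
        if self.delta < -BOOST_NATS:
            return "reduction"
        return "ambiguous"


def select_matched_mdn(mdn_tmap: StatMap, mdn_mask: ROIMask, n: int) -> ROIMask:
    """The ``n`` most activated MDN voxels, matching a candidate ROI size.

    Voxels are ranked by the Hard > Easy t value inside the MDN mask; ties
    break deterministically by flat voxel index (lower index first).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > mdn_mask.n_voxels:
        raise ValueError(
            f"requested {n} voxels but MDN mask has {mdn_mask.n_voxels}"
        )
    tvals = np.asarray(mdn_tmap.values, dtype=float)
    flat_idx = np.flatnonzero(mdn_mask.mask.ravel())
    t_in = tvals.ravel()[flat_idx]
    t_in = np.where(np.isfinite(t_in), t_in, -np.inf)
    order = np.lexsort((flat_idx, -t_in))
    chosen = flat_idx[order[:n]]
    mask = np.zeros(mdn_mask.mask.shape, dtype=bool)
    mask.ravel()[chosen] = True
    return ROIMask(mask=mask, label=f"{mdn_mask.label}_top{n}",
                   affine=mdn_mask.affine)


def compare_models(joint_fit: MVBResult, single_fit: MVBResult) -> ModelComparison:
    """Log-evidence difference and boost category for one participant."""
    return ModelComparison(
        logev_joint=joint_fit.log_evidence,
        logev_single=single_fit.log_evidence,
    )


def weight_spread(fit: MVBResult, voxel_indices: np.ndarray | None = None) -> float:
    """Standard deviation of posterior decoding weights over an ROI.

    ``voxel_indices`` selects the ROI's columns within the fitted model
    (e.g. the candidate-ROI half of a joint model); ``None`` uses all
    weights.  Population standard deviation (ddof=0).
    """
    w = fit.weights if voxel_indices is None else fit.weights[voxel_indices]
    if w.size < 2:
        raise ValueError("spread needs at least 2 voxels")
    return float(np.std(w))


def build_group_table(
    records: list[ParticipantRecord],
    comparisons: list[ModelComparison],
    spreads: list[float],
    univariate: np.ndarray,
    reliable: list[bool] | None = None,
) -> pd.DataFrame:
    """Assemble the per-participant table feeding the group models."""
    if not (len(records) == len(comparisons) == len(spreads) == len(univariate)):
        raise ValueError("inputs must align one row per participant")
    if reliable is None:
        reliable = [True] * len(records)
    return pd.DataFrame(
        dict(
            participant_id=[r.id for r in records],
            z_age=[r.z_age for r in records],
            sex=[r.sex for r in records],
            z_performance=[r.z_performance for r in records],
            univariate=np.asarray(univariate, dtype=float),
            delta=[c.delta for c in comparisons],
            category=[c.category for c in comparisons],
            spread=spreads,
            reliable=reliable,
        )
    )


def _standardised_predictors(table: pd.DataFrame) -> np.ndarray:
    z_age = table["z_age"].to_numpy(dtype=float)
    sex_raw = (table["sex"] == "M").to_numpy(dtype=float)
    sex = (sex_raw - sex_raw.mean()) / sex_raw.std() if sex_raw.std() > 0 else sex_raw - sex_raw.mean()
    uni = table["univariate"].to_numpy(dtype=float)
    uni = (uni - uni.mean()) / uni.std() if uni.std() > 0 else uni - uni.mean()
    return np.column_stack([np.ones(len(table)), z_age, sex, uni])


BOOST_TERMS = ["const", "age", "sex", "univariate"]


def boost_model(table: pd.DataFrame, ordinal: bool = False) -> pd.DataFrame:
    """Logistic regression of boost likelihood on age.

    Only reliable participants enter.  The default is a binary logistic
    model of boost vs ambiguous (reductions, if any, raise unless
    ``ordinal`` is set, in which case an ordered logit over
    reduction < ambiguous < boost is fit).  Covariates: standardised sex
    and the region's mean univariate activation.  Returns estimates, z, p
    and odds ratios per term.
    """
    import statsmodels.api as sm

    data = table[table["reliable"]].reset_index(drop=True)
    cats = set(data["category"])
    if "reduction" in cats and not ordinal:
        raise ValueError(
            "reduction outcomes present; use ordinal=True for an ordered fit"
        )
    x = _standardised_predictors(data)
    if ordinal:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        order = pd.Categorical(
            data["category"],
            categories=["reduction", "ambiguous", "boost"],
            ordered=True,
        )
        fit = OrderedModel(order.codes, x[:, 1:], distr="logit").fit(
            method="bfgs", disp=False, maxiter=500
        )
        params = fit.params[: x.shape[1] - 1]
        table_out = pd.DataFrame(
            dict(
                term=BOOST_TERMS[1:],
                estimate=params,
                z=fit.tvalues[: x.shape[1] - 1],
                p=fit.pvalues[: x.shape[1] - 1],
                odds_ratio=np.exp(params),
            )
        )
        table_out.attrs["model"] = "ordinal_logit"
        return table_out

    outcome = (data["category"] == "boost").to_numpy(dtype=float)
    if outcome.min() == outcome.max():
        raise ValueError("both boost and ambiguous outcomes must be present")
    separated = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(outcome, x).fit(disp=False, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 15):
            separated = True
    except Exception:  # PerfectSeparationError and numerical failures
        separated = True
    if separated:
        logger.warning("boost_model: outcome separation; penalised fallback")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, fit_intercept=False).fit(x, outcome)
        params = lr.coef_[0]
        out = pd.DataFrame(
            dict(
                term=BOOST_TERMS,
                estimate=params,
                z=np.full(len(params), np.nan),
                p=np.full(len(params), np.nan),
                odds_ratio=np.exp(params),
            )
        )
        out.attrs["separated"] = True
        return out
    out = pd.DataFrame(
        dict(
            term=BOOST_TERMS,
            estimate=fit.params,
            z=fit.tvalues,
            p=fit.pvalues,
            odds_ratio=np.exp(fit.params),
        )
    )
    out.attrs["separated"] = False
    out.attrs["n"] = int(len(data))
    return out


def spread_model(table: pd.DataFrame, standardise_outcome: bool = True) -> pd.DataFrame:
    """Linear regression of weight spread on age (sex and univariate
    activation as covariates), over reliable participants."""
    import statsmodels.api as sm

    data = table[table["reliable"]].reset_index(drop=True)
    if len(data) < 3:
        raise ValueError("need at least 3 reliable participants")
    y = data["spread"].to_numpy(dtype=float)
    if standardise_outcome:
        if y.std() == 0:
            raise ValueError("spread is constant")
        y = (y - y.mean()) / y.std()
    x = _standardised_predictors(data)
    fit = sm.OLS(y, x).fit()
    out = pd.DataFrame(
        dict(
            term=BOOST_TERMS,
            estimate=fit.params,
            t=fit.tvalues,
            p=fit.pvalues,
        )
    )
    out.attrs["n"] = int(len(data))
    return out
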