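"""Normative puberty-age models and the puberty age gap.

The central object is :class:`PubertyAgeModel`: built from a preprocessed,
family-stratified cohort plus its TD / non-TD partition, its :meth:`fit`
runs the full normative procedure for one sex and feature set —

1. 10-fold cross-validated additive-model age predictions for every
   typically developing (TD) observation (penalties tuned by GCV inside
   each training split only);
2. a final model trained on the complete TD sample, used to predict age in
   the non-TD sample;
3. a regression-to-the-mean (RTM) bias correction: the raw residual
   (prediction minus age) is regressed on age over the TD out-of-sample
   predictions and that linear trend is removed from everyone.

The bias-adjusted prediction is the *puberty age*; puberty age minus
chronological age is the *puberty age gap* (positive = earlier-than-peers
development).  ``model="linear"`` runs the traditional baseline instead:
per-fold OLS of age on the total PDS score, with the same folds and the
same RTM correction for symmetry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from pubertyage.gam import AdditiveAgeModel, AdditiveAgeResults, default_penalty_grid
from pubertyage.preprocessing import FeatureSet, SamplePartition, build_feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PubertyAgeModel",
    "PubertyAgeResults",
    "crossval_predict",
    "predict_nontd",
    "correct_rtm_bias",
    "fit_linear_baseline",
    "MODEL_NAMES",
]

MODEL_NAMES = ("physical", "hormonal", "combined", "linear")


# ----------------------------------------------------------------------
# functional layer
# ----------------------------------------------------------------------

def _check_folds(age: np.ndarray, folds) -> None:
    for i, (_, test_idx) in enumerate(folds):
        if np.unique(age[test_idx]).size < 2:
            raise ValueError(f"fold {i} has fewer than 2 distinct ages")


def crossval_predict(
    td_features: pd.DataFrame,
    td_age,
    k: int = 10,
    seed: int = 0,
    penalty_grid=None,
    n_basis: int = 10,
):
    """Out-of-sample additive-model age predictions for every TD row.

    Rows are partitioned into ``k`` near-equal, seeded folds; for each fold
    the model (including its GCV penalty tuning) is fitted on the other
    ``k - 1`` folds and used to predict the held-out fold.  Returns
    ``(predictions, fold_index, fold_fits)`` aligned with the input rows.
    """
    age = np.asarray(td_age, float)
    n = len(td_features)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))
    _check_folds(age, splits)
    preds = np.full(n, np.nan)
    fold_idx = np.full(n, -1)
    fits: list[AdditiveAgeResults] = []
    for i, (train, test) in enumerate(splits):
        m = AdditiveAgeModel(td_features.iloc[train], age[train], n_basis=n_basis)
        res = m.fit(penalty_grid=penalty_grid)
        preds[test] = res.predict(td_features.iloc[test])
        fold_idx[test] = i
        fits.append(res)
    return preds, fold_idx, fits


def predict_nontd(full_td_fit: AdditiveAgeResults, nontd_features: pd.DataFrame) -> np.ndarray:
    """Apply the complete-TD fit to the non-TD rows (deterministic)."""
    if len(nontd_features) == 0:
        return np.empty(0)
    return full_td_fit.predict(nontd_features)


def correct_rtm_bias(raw_predictions, ages, reference_mask):
    """Remove the regression-to-the-mean age trend from the raw residuals.

    An OLS of the raw gap (prediction - age) on age is fitted over the
    reference rows (the TD out-of-sample predictions) and its fitted line
    is subtracted from every row's raw gap.  Returns
    ``(puberty_age, gap, (intercept, slope))``.
    """
    pred = np.asarray(raw_predictions, float)
    age = np.asarray(ages, float)
    ref = np.asarray(reference_mask, bool)
    if ref.sum() < 2 or np.var(age[ref]) == 0:
        raise ValueError("reference set must contain at least 2 distinct ages")
    raw_gap = pred - age
    b, a = np.polyfit(age[ref], raw_gap[ref], 1)
    gap = raw_gap - (a + b * age)
    puberty_age = age + gap
    return puberty_age, gap, (float(a), float(b))


def fit_linear_baseline(
    total_pds,
    age,
    k: int = 10,
    seed: int = 0,
):
    """Traditional pubertal-timing baseline: per-fold OLS of age on total PDS.

    Uses the same seeded fold construction as :func:`crossval_predict`, so
    absolute errors are comparable row-for-row with the additive model run
    on the identical row set.  Returns ``(predictions, fold_index, coefs)``
    where ``coefs`` holds each fold's (intercept, slope).
    """
    x = np.asarray(total_pds, float)
    y = np.asarray(age, float)
    n = x.size
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and n >= k")
    splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))
    _check_folds(y, splits)
    preds = np.full(n, np.nan)
    fold_idx = np.full(n, -1)
    coefs = []
    for i, (train, test) in enumerate(splits):
        if np.var(x[train]) == 0:
            raise ValueError(f"zero-variance total PDS in training fold {i}")
        slope, intercept = np.polyfit(x[train], y[train], 1)
        preds[test] = intercept + slope * x[test]
        fold_idx[test] = i
        coefs.append((float(intercept), float(slope)))
    return preds, fold_idx, coefs


# ----------------------------------------------------------------------
# model / results layer
# ----------------------------------------------------------------------

class PubertyAgeModel:
    """Normative pubertal-timing model for one sex and feature set.

    Parameters
    ----------
    data : DataFrame
        Preprocessed, family-stratified cohort (one observation per
        family) with cleaned hormone columns.
    partition : SamplePartition
        TD / non-TD observation ids over ``data``.
    model : {"physical", "hormonal", "combined", "linear"}
        Feature set; ``"linear"`` is the traditional total-PDS OLS baseline.
    sex : {"F", "M"}
    """

    def __init__(
        self,
        data: pd.DataFrame,
        partition: SamplePartition,
        model: str = "combined",
        sex: str = "F",
        n_basis: int = 10,
    ):
        if model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}, got {model!r}")
        if sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
        self.data = data
        self.partition = partition
        self.model_name = model
        self.sex = sex
        self.n_basis = n_basis

        fs = FeatureSet("physical" if model == "linear" else model)
        X, age, ids = build_feature_matrix(data, fs, sex)
        if model == "linear":
            X = X.sum(axis=1).to_frame("total_pds")
        td_set = set(partition.td_ids)
        nontd_set = set(partition.nontd_ids)
        is_td = ids.isin(td_set).to_numpy()
        is_nontd = ids.isin(nontd_set).to_numpy()
        self.X_td, self.age_td, self.ids_td = X[is_td], age[is_td], ids[is_td]
        self.X_nontd, self.age_nontd, self.ids_nontd = X[is_nontd], age[is_nontd], ids[is_nontd]

    def fit(self, k: int = 10, seed: int = 0, penalty_grid=None) -> "PubertyAgeResults":
        grid = default_penalty_grid() if penalty_grid is None else penalty_grid
        age_td = self.age_td.to_numpy()
        if self.model_name == "linear":
            x = self.X_td["total_pds"]
            preds_td, fold_idx, coefs = fit_linear_baseline(x, age_td, k=k, seed=seed)
            slope, intercept = np.polyfit(x, age_td, 1)
            full_fit = ("ols", float(intercept), float(slope))
            preds_nontd = (
                intercept + slope * self.X_nontd["total_pds"].to_numpy()
                if len(self.X_nontd)
                else np.empty(0)
            )
            fold_fits: list = [("ols",) + c for c in coefs]
        else:
            preds_td, fold_idx, fold_fits = crossval_predict(
                self.X_td, age_td, k=k, seed=seed, penalty_grid=grid, n_basis=self.n_basis
            )
            full_model = AdditiveAgeModel(self.X_td, age_td, n_basis=self.n_basis)
            full_fit = full_model.fit(penalty_grid=grid)
            preds_nontd = predict_nontd(full_fit, self.X_nontd)

        all_pred = np.concatenate([preds_td, preds_nontd])
        all_age = np.concatenate([age_td, self.age_nontd.to_numpy()])
        ref = np.concatenate(
            [np.ones(len(preds_td), bool), np.zeros(len(preds_nontd), bool)]
        )
        puberty_age, gap, rtm = correct_rtm_bias(all_pred, all_age, ref)
        frame = pd.DataFrame(
            {
                "observation_id": np.concatenate(
                    [self.ids_td.to_numpy(), self.ids_nontd.to_numpy()]
                ),
                "sex": self.sex,
                "model": self.model_name,
                "fold": [str(f) for f in fold_idx] + ["nonTD"] * len(preds_nontd),
                "age": all_age,
                "raw_prediction": all_pred,
                "puberty_age": puberty_age,
                "gap": gap,
            }
        )
        return PubertyAgeResults(self, frame, fold_fits, full_fit, rtm, k, seed)


@dataclass
class PubertyAgeResults:
    """Fitted normative model: per-observation puberty age and gap.

    ``gap_frame`` has one row per scored observation with columns
    observation_id, sex, model, fold ("nonTD" for the non-TD sample), age,
    raw_prediction, puberty_age and gap (= puberty_age - age).
    """

    model: PubertyAgeModel
    gap_frame: pd.DataFrame
    fold_fits: list
    full_fit: object
    rtm_coef: tuple[float, float]
    k: int
    seed: int

    @property
    def td_frame(self) -> pd.DataFrame:
        return self.gap_frame[self.gap_frame["fold"] != "nonTD"]

    def partial_dependence(self, feature: str, n_grid: int = 50):
        if isinstance(self.full_fit, AdditiveAgeResults):
            return self.full_fit.partial_dependence(feature, n_grid)
        raise ValueError("partial dependence is only defined for additive-model fits")

    def summary(self) -> str:
        td = self.td_frame
        r = np.corrcoef(td["puberty_age"], td["age"])[0, 1]
        mae_v = np.abs(td["gap"]).mean()
        a, b = self.rtm_coef
        lines = [
            f"Puberty age model [{self.model.model_name} / {self.model.sex}]",
            f"  TD out-of-sample n = {len(td)}, non-TD n = {len(self.gap_frame) - len(td)}",
            f"  {self.k}-fold CV (seed {self.seed})",
            f"  TD out-of-sample r = {r:.3f}, MAE = {mae_v:.3f} yr",
            f"  RTM correction: raw gap = {a:.3f} + {b:.3f} * age (removed)",
        ]
        if isinstance(self.full_fit, AdditiveAgeResults):
            lam = ", ".join(f"{k2}={v:.3g}" for k2, v in self.full_fit.lambdas.items())
            lines.append(f"  full-TD fit penalties: {lam}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.gap_frame.to_csv(path, index=False)

    def fit_summary_json(self, path) -> None:
        d = {
            "model": self.model.model_name,
            "sex": self.model.sex,
            "k": self.k,
            "seed": self.seed,
            "rtm_intercept": self.rtm_coef[0],
            "rtm_slope": self.rtm_coef[1],
        }
        if isinstance(self.full_fit, AdditiveAgeResults):
            d["lambdas"] = self.full_fit.lambdas
            d["gcv"] = self.full_fit.gcv_score
            d["grid_trace_len"] = len(self.full_fit.grid)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
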