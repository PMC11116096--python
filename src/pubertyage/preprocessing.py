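"""Raw cohort records -> model-ready feature matrices.

Covers hormone confound cleaning (mixed-model residualization on the log
scale), PDS coding (menarche recoded 1/4), the typically-developing (TD)
partition based on DSM-oriented scale scores, one-observation-per-family
stratification, empirical BMI z-scores, and assembly of the per-sex feature
matrices for the three normative feature sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pubertyage.lmm import fit_random_intercept
from pubertyage.simulate import CONFOUNDS, DSM_SCALES, FEMALE_PDS, MALE_PDS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "SamplePartition",
    "code_menarche",
    "clean_hormones",
    "select_td",
    "stratify_families",
    "bmi_zscore",
    "build_feature_matrix",
    "preprocess",
    "HORMONE_FEATURES",
]

HORMONE_FEATURES = ("dhea_clean", "tst_clean")

#: physical features per sex; menarche (coded 1/4) is a fifth female item
PHYSICAL_FEATURES = {
    "F": list(FEMALE_PDS) + ["menarche_coded"],
    "M": list(MALE_PDS),
}


@dataclass(frozen=True)
class FeatureSet:
    """A named, ordered feature list for one normative model.

    ``physical`` uses the sex-appropriate PDS items only, ``hormonal`` the
    two cleaned log-hormones, and ``combined`` their union.
    """

    name: str

    _VALID = ("physical", "hormonal", "combined")

    def __post_init__(self):
        if self.name not in self._VALID:
            raise ValueError(f"feature set must be one of {self._VALID}, got {self.name!r}")

    def columns(self, sex: str) -> list[str]:
        if sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
        if self.name == "physical":
            return list(PHYSICAL_FEATURES[sex])
        if self.name == "hormonal":
            return list(HORMONE_FEATURES)
        return list(PHYSICAL_FEATURES[sex]) + list(HORMONE_FEATURES)


@dataclass
class SamplePartition:
    """TD / non-TD split of the family-stratified sample."""

    td_ids: list[str]
    nontd_ids: list[str]
    unassignable_ids: list[str] = field(default_factory=list)
    stratification_seed: int | None = None
    threshold: float = 60.0

    def __post_init__(self):
        overlap = set(self.td_ids) & set(self.nontd_ids)
        if overlap:
            raise ValueError(f"TD and non-TD sets overlap: {sorted(overlap)[:5]} ...")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "td_ids": list(self.td_ids),
                    "nontd_ids": list(self.nontd_ids),
                    "unassignable_ids": list(self.unassignable_ids),
                    "stratification_seed": self.stratification_seed,
                    "threshold": self.threshold,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SamplePartition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def code_menarche(response: str):
    """Recode the binary menarche response onto the ordinal PDS scale.

    "no" -> 1, "yes" -> 4.  Missing input (NaN) propagates as NaN; anything
    else is rejected.
    """
    if isinstance(response, float) and np.isnan(response):
        return np.nan
    if response == "no":
        return 1
    if response == "yes":
        return 4
    raise ValueError(f"menarche response must be 'yes' or 'no', got {response!r}")


def clean_hormones(
    records: pd.DataFrame,
    hormones: tuple[str, ...] = ("dhea", "tst"),
    confounds: tuple[str, ...] = CONFOUNDS,
) -> pd.DataFrame:
    """Residualize log-hormones on collection-context confounds.

    Per sex and hormone, a linear mixed model of the log hormone on the five
    collection confounds (fixed effects) with a subject-level random
    intercept is fitted; the cleaned value is the observed log hormone minus
    the fitted fixed-effect confound contribution (grand intercept
    retained), then centered and scaled within sex.  New columns
    ``<hormone>_clean`` are added; input columns are untouched.

    Cohorts with a single subject (no grouping information) fall back to a
    fixed-effects-only OLS fit with a logged warning.
    """
    out = records.copy()
    for horm in hormones:
        vals = records[horm]
        if (vals.dropna() <= 0).any():
            bad = records.loc[vals.notna() & (vals <= 0)].index[:5].tolist()
            raise ValueError(f"non-positive {horm} values at rows {bad}")
        out[f"{horm}_clean"] = np.nan

    for sex in ("F", "M"):
        sex_mask = records["sex"] == sex
        for horm in hormones:
            ok = sex_mask & records[horm].notna()
            for c in confounds:
                ok &= records[c].notna()
            sub = records.loc[ok]
            if len(sub) < len(confounds) + 2:
                continue
            y = np.log(sub[horm].to_numpy(float))
            X = sub.loc[:, list(confounds)].to_numpy(float)
            Xc = X - X.mean(axis=0)  # center so the grand intercept is clean
            exog = sm.add_constant(Xc)
            groups = sub["subject_id"]
            if groups.nunique() < 2:
                logger.warning(
                    "single-subject input for %s (%s): falling back to OLS cleaning",
                    horm,
                    sex,
                )
                params = sm.OLS(y, exog).fit().params
            else:
                res = fit_random_intercept(y, exog, groups.to_numpy())
                if not np.all(np.isfinite(res.params)):
                    raise RuntimeError(
                        f"singular mixed-model fit cleaning {horm} ({sex}); "
                        f"params={res.params}"
                    )
                params = res.params
            cleaned = y - Xc @ np.asarray(params)[1:]  # keep grand intercept
            mu, sd = cleaned.mean(), cleaned.std(ddof=0)
            if sd == 0:
                sd = 1.0
            out.loc[ok, f"{horm}_clean"] = (cleaned - mu) / sd
    return out


def select_td(records: pd.DataFrame, threshold: float = 60.0) -> SamplePartition:
    """Partition observations into typically developing (TD) vs non-TD.

    TD iff all six DSM-oriented scale scores are <= ``threshold`` (a score
    strictly above the threshold excludes).  Observations missing any DSM
    score are unassignable and reported separately.
    """
    if records.empty:
        return SamplePartition([], [], threshold=threshold)
    dsm = records.loc[:, list(DSM_SCALES)]
    missing = dsm.isna().any(axis=1)
    td = (dsm.le(threshold).all(axis=1)) & ~missing
    ids = records["observation_id"]
    part = SamplePartition(
        td_ids=ids[td].tolist(),
        nontd_ids=ids[~td & ~missing].tolist(),
        unassignable_ids=ids[missing].tolist(),
        threshold=threshold,
    )
    if missing.any():
        logger.warning("%d observations missing DSM scores are unassignable", missing.sum())
    return part


def stratify_families(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep a single, uniformly random observation per family.

    Removes familial clustering (siblings and repeat waves) prior to
    normative modelling.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    # order by family then stable position so the draw is reproducible
    idx = records.index.to_numpy()
    fam = records["family_id"].to_numpy()
    order = np.argsort(fam, kind="stable")
    keep = []
    start = 0
    fam_sorted = fam[order]
    for end in range(1, len(order) + 1):
        if end == len(order) or fam_sorted[end] != fam_sorted[start]:
            group = order[start:end]
            keep.append(idx[group[rng.integers(0, len(group))]])
            start = end
    return records.loc[keep].sort_index()


def bmi_zscore(records: pd.DataFrame, min_bin: int = 10) -> pd.DataFrame:
    """Empirical BMI z-scores within sex x 1-year age bins.

    Standardizes BMI against the input sample itself (an internal norm,
    not an external growth chart).  Bins with fewer than ``min_bin``
    records are merged into their nearest neighbouring bin, with a log
    message.  Adds a ``bmi_z`` column.
    """
    if "bmi" not in records.columns:
        raise ValueError("records must contain a 'bmi' column")
    out = records.copy()
    out["bmi_z"] = np.nan
    for sex in ("F", "M"):
        mask = (out["sex"] == sex) & out["bmi"].notna() & out["age"].notna()
        if not mask.any():
            continue
        bins = np.floor(out.loc[mask, "age"]).astype(int)
        counts = bins.value_counts()
        valid = sorted(b for b, c in counts.items() if c >= min_bin)

        def _map(b):
            # sparse bins borrow the nearest well-populated neighbour
            if not valid or b in valid:
                return b
            nearest = min(valid, key=lambda v: (abs(v - b), v))
            logger.info("BMI bin %s (%s, n=%d) merged into bin %s", b, sex, counts[b], nearest)
            return nearest

        mapped = bins.map(_map)
        for _, grp_idx in mapped.groupby(mapped).groups.items():
            vals = out.loc[grp_idx, "bmi"]
            mu, sd = vals.mean(), vals.std(ddof=0)
            out.loc[grp_idx, "bmi_z"] = 0.0 if sd == 0 else (vals - mu) / sd
    return out


def build_feature_matrix(
    records: pd.DataFrame,
    feature_set: FeatureSet,
    sex: str,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Assemble the (X, age, ids) design for one sex and feature set.

    Filters to the requested sex, codes menarche onto the 1-4 scale when the
    physical set for females is requested, and keeps complete cases only.
    Returns ``(X, age, observation_ids)`` with a fixed column order.
    Raises if no complete rows remain, reporting per-column missingness.
    """
    sub = records.loc[records["sex"] == sex].copy()
    if feature_set.name in ("physical", "combined") and sex == "F":
        sub["menarche_coded"] = sub["menarche"].map(
            lambda r: code_menarche(r) if r in ("yes", "no") else np.nan
        )
    cols = feature_set.columns(sex)
    missing_cols = [c for c in cols if c not in sub.columns]
    if missing_cols:
        raise ValueError(f"missing feature columns: {missing_cols}")
    complete = sub.loc[:, cols].notna().all(axis=1) & sub["age"].notna()
    if not complete.any():
        tally = sub.loc[:, cols].isna().sum().to_dict()
        raise ValueError(f"no complete-case rows for {feature_set.name}/{sex}; missing per column: {tally}")
    kept = sub.loc[complete]
    X = kept.loc[:, cols].astype(float)
    return X, kept["age"].astype(float), kept["observation_id"]


def preprocess(
    records: pd.DataFrame,
    seed: int,
    td_threshold: float = 60.0,
) -> tuple[pd.DataFrame, SamplePartition]:
    """Full preprocessing stage: clean hormones, BMI z, stratify, TD split.

    Hormone cleaning and BMI standardization use all observations (they are
    per-observation transforms); the family stratification then keeps one
    observation per family, and the TD partition is taken over the
    stratified sample.
    """
    cleaned = clean_hormones(records)
    cleaned = bmi_zscore(cleaned)
    strat = stratify_families(cleaned, seed=seed)
    part = select_td(strat, threshold=td_threshold)
    part.stratification_seed = seed
    return strat, part
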