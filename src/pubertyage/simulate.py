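"""Synthetic longitudinal cohort generator with known pubertal timing.

The generator emulates the statistical structure of a large multi-site
adolescent cohort: families (possibly with siblings) recruited at ~21 sites,
children aged 9-10 at baseline with annual follow-up waves, ordinal Pubertal
Development Scale (PDS) item responses, right-skewed salivary hormones
(DHEA, testosterone) contaminated by collection-context confounds, and
T-score-like mental-health outcome scales with site-level random intercepts.

Each subject carries a latent *timing* offset (years).  Maturation at age
``a`` is ``logistic((a - mu_sex + timing) / s)``, so a positive offset means
the child matures *earlier* than same-sex peers.  The offset is stored on
every record (``truth_timing``) and is the ground truth that the downstream
puberty-age-gap pipeline should recover.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "sample_pds_items",
    "write_cohort",
    "read_cohort",
    "PDS_ITEMS",
    "FEMALE_PDS",
    "MALE_PDS",
    "CBCL_SYNDROMES",
    "CBCL_BROAD",
    "DSM_SCALES",
    "OUTCOME_COLUMNS",
]

# PDS item names per sex; menarche is handled separately (binary).
SHARED_PDS = ("pds_growth", "pds_body_hair", "pds_skin")
FEMALE_PDS = SHARED_PDS + ("pds_breast",)
MALE_PDS = SHARED_PDS + ("pds_voice", "pds_facial_hair")
PDS_ITEMS = SHARED_PDS + ("pds_breast", "pds_voice", "pds_facial_hair")

CBCL_SYNDROMES = (
    "cbcl_anxdep",
    "cbcl_withdep",
    "cbcl_somatic",
    "cbcl_social",
    "cbcl_thought",
    "cbcl_attention",
    "cbcl_rulebreak",
    "cbcl_aggressive",
)
CBCL_BROAD = ("cbcl_internalizing", "cbcl_externalizing", "cbcl_totprob")
DSM_SCALES = (
    "dsm_affective",
    "dsm_anxiety",
    "dsm_somatic",
    "dsm_adhd",
    "dsm_opposit",
    "dsm_conduct",
)
OUTCOME_COLUMNS = CBCL_SYNDROMES + CBCL_BROAD

CONFOUNDS = (
    "collection_time",
    "collection_duration",
    "wake_time",
    "exercised",
    "caffeine",
)
# Centers used when the confound terms enter the log-hormone model, so that
# nonzero confound effects do not shift the overall hormone level.
_CONFOUND_CENTERS = {
    "collection_time": 9.0,
    "collection_duration": 30.0,
    "wake_time": 7.0,
    "exercised": 0.0,
    "caffeine": 0.0,
}

_DEFAULT_CUTPOINTS: dict[str, tuple[float, ...]] = {
    "pds_growth": (0.25, 0.50, 0.75),
    "pds_body_hair": (0.30, 0.55, 0.80),
    "pds_skin": (0.20, 0.45, 0.70),
    "pds_breast": (0.25, 0.50, 0.75),
    "pds_voice": (0.35, 0.60, 0.85),
    "pds_facial_hair": (0.45, 0.70, 0.90),
}
_MENARCHE_CUTPOINT = 0.60

RACE_CATEGORIES = ("White", "Black", "Hispanic", "Asian", "Other")
_RACE_PROBS = (0.52, 0.15, 0.20, 0.02, 0.11)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Identical config + seed produces a bit-identical cohort.
    """

    n_families: int
    sibling_prob: float = 0.15
    n_waves: int = 4
    n_sites: int = 21
    age_baseline_range: tuple[float, float] = (9.0, 10.0)
    wave_gap: float = 1.0
    female_prob: float = 0.47
    # latent timing offset (years): positive = earlier maturation
    timing_sd: float = 0.75
    # dimensionless log-tempo spread; positive draw = faster progression
    tempo_sd: float = 0.10
    # logistic maturation curve: sex-specific midpoints (F, M) and scale
    maturation_midpoints: tuple[float, float] = (10.8, 12.0)
    maturation_scale: float = 1.5
    # ordinal noise added to maturation before item thresholding
    pds_noise_sd: float = 0.05
    pds_cutpoints: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CUTPOINTS)
    )
    menarche_cutpoint: float = _MENARCHE_CUTPOINT
    # log-scale residual SD of hormones
    hormone_noise_sd: float = 0.25
    # (linear, saturating) coefficients of maturation in each log-hormone
    hormone_slopes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"dhea": (1.2, 0.8), "tst": (1.5, 1.0)}
    )
    # additive log-scale confound coefficients
    confound_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "collection_time": 0.03,
            "collection_duration": 0.001,
            "wake_time": -0.02,
            "exercised": -0.10,
            "caffeine": -0.08,
        }
    )
    # standardized effect of latent timing on every outcome scale
    outcome_effect: float = 0.3
    # optional age-moderation of the timing effect (per year around age 11)
    outcome_effect_age_slope: float = 0.0
    outcome_sd: float = 10.0
    # share of outcome noise variance from a subject-level general factor
    # (induces the cross-scale correlation CBCL-type scores exhibit)
    outcome_corr: float = 0.5
    site_sd: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("sibling_prob", "female_prob", "missing_rate", "outcome_corr"):
            p = getattr(self, name)
            if not np.isfinite(p) or not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p!r}")
        for name in (
            "timing_sd",
            "tempo_sd",
            "pds_noise_sd",
            "hormone_noise_sd",
            "outcome_sd",
            "site_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.maturation_scale <= 0:
            raise ValueError("maturation_scale must be > 0")
        lo, hi = self.age_baseline_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("age_baseline_range must be a finite (lo, hi) with lo <= hi")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pds_cutpoints"] = {k: list(v) for k, v in self.pds_cutpoints.items()}
        d["hormone_slopes"] = {k: list(v) for k, v in self.hormone_slopes.items()}
        d["confound_effects"] = dict(self.confound_effects)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "age_baseline_range" in d:
            d["age_baseline_range"] = tuple(d["age_baseline_range"])
        if "maturation_midpoints" in d:
            d["maturation_midpoints"] = tuple(d["maturation_midpoints"])
        if "pds_cutpoints" in d:
            d["pds_cutpoints"] = {k: tuple(v) for k, v in d["pds_cutpoints"].items()}
        if "hormone_slopes" in d:
            d["hormone_slopes"] = {k: tuple(v) for k, v in d["hormone_slopes"].items()}
        return cls(**d)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sample_pds_items(
    maturation: float,
    sex: str,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    cutpoints: Mapping[str, Sequence[float]] | None = None,
    menarche_cutpoint: float = _MENARCHE_CUTPOINT,
) -> tuple[dict[str, int], str]:
    """Emit ordinal PDS item responses for one observation.

    Each item equals 1 plus the number of its cutpoints strictly below the
    (noise-perturbed) maturation score.  For females the menarche flag is
    "yes" iff maturation exceeds its cutpoint.

    Returns ``(items, menarche)`` where ``menarche`` is "yes"/"no" for
    females and "n/a" for males.
    """
    if not 0.0 <= maturation <= 1.0:
        raise ValueError(f"maturation must lie in [0, 1], got {maturation!r}")
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    cuts = dict(_DEFAULT_CUTPOINTS) if cutpoints is None else cutpoints
    names = FEMALE_PDS if sex == "F" else MALE_PDS
    items: dict[str, int] = {}
    for name in names:
        m = maturation
        if noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            m = float(np.clip(m + rng.normal(0.0, noise_sd), 0.0, 1.0))
        items[name] = 1 + int(np.sum(np.asarray(cuts[name]) < m))
    if sex == "F":
        m = maturation
        if noise_sd > 0:
            m = float(np.clip(m + rng.normal(0.0, noise_sd), 0.0, 1.0))
        menarche = "yes" if m > menarche_cutpoint else "no"
    else:
        menarche = "n/a"
    return items, menarche


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a longitudinal cohort as one DataFrame row per observation.

    See module docstring for the data-generating model.  Ground-truth columns
    are prefixed ``truth_`` so downstream stages can drop them wholesale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- families, subjects, sites ---------------------------------------
    n_children = 1 + (rng.random(config.n_families) < config.sibling_prob).astype(int)
    family_of_subject = np.repeat(np.arange(config.n_families), n_children)
    n_subj = family_of_subject.size
    site_of_family = rng.integers(0, config.n_sites, size=config.n_families)
    site = site_of_family[family_of_subject]

    sex = np.where(rng.random(n_subj) < config.female_prob, "F", "M")
    lo, hi = config.age_baseline_range
    age0 = rng.uniform(lo, hi, size=n_subj)
    timing = (
        rng.normal(0.0, config.timing_sd, size=n_subj)
        if config.timing_sd > 0
        else np.zeros(n_subj)
    )
    tempo = (
        rng.normal(0.0, config.tempo_sd, size=n_subj)
        if config.tempo_sd > 0
        else np.zeros(n_subj)
    )
    race = rng.choice(len(RACE_CATEGORIES), size=config.n_families, p=_RACE_PROBS)[
        family_of_subject
    ]
    ses_income = rng.integers(1, 11, size=config.n_families)[family_of_subject]
    ses_education = rng.integers(1, 6, size=config.n_families)[family_of_subject]
    bmi_base = rng.normal(0.0, 2.0, size=n_subj)

    mu_f, mu_m = config.maturation_midpoints
    mu = np.where(sex == "F", mu_f, mu_m)
    scale = config.maturation_scale / np.exp(tempo)  # positive tempo = faster

    n_obs = n_subj * config.n_waves
    subj_idx = np.repeat(np.arange(n_subj), config.n_waves)
    wave = np.tile(np.arange(config.n_waves), n_subj)
    age = age0[subj_idx] + config.wave_gap * wave
    maturation = _logistic((age - mu[subj_idx] + timing[subj_idx]) / scale[subj_idx])

    # --- PDS items (vectorized thresholding with ordinal noise) -----------
    cuts = config.pds_cutpoints
    sex_obs = sex[subj_idx]
    pds = {}
    for item in PDS_ITEMS:
        applies = (
            np.isin(sex_obs, ["F", "M"])
            if item in SHARED_PDS
            else (sex_obs == ("F" if item == "pds_breast" else "M"))
        )
        noisy = maturation
        if config.pds_noise_sd > 0:
            noisy = np.clip(
                maturation + rng.normal(0.0, config.pds_noise_sd, size=n_obs), 0.0, 1.0
            )
        val = 1 + (noisy[:, None] > np.asarray(cuts[item])[None, :]).sum(axis=1)
        pds[item] = np.where(applies, val.astype(float), np.nan)

    men_noisy = maturation
    if config.pds_noise_sd > 0:
        men_noisy = np.clip(
            maturation + rng.normal(0.0, config.pds_noise_sd, size=n_obs), 0.0, 1.0
        )
    men_flag = men_noisy > config.menarche_cutpoint
    # menarche is an absorbing state: once reached, stays "yes" in later waves
    men_flag = (
        pd.Series(men_flag).groupby(subj_idx).cummax().to_numpy().astype(bool)
    )
    menarche = np.where(sex_obs == "F", np.where(men_flag, "yes", "no"), "n/a")

    # --- hormones with collection-context confounds ----------------------
    collection_time = np.clip(rng.normal(9.0, 1.5, size=n_obs), 6.0, 20.0)
    collection_duration = np.clip(rng.normal(30.0, 10.0, size=n_obs), 5.0, 90.0)
    wake_time = np.clip(rng.normal(7.0, 1.0, size=n_obs), 4.0, 12.0)
    exercised = (rng.random(n_obs) < 0.30).astype(int)
    caffeine = (rng.random(n_obs) < 0.20).astype(int)
    conf_vals = {
        "collection_time": collection_time,
        "collection_duration": collection_duration,
        "wake_time": wake_time,
        "exercised": exercised,
        "caffeine": caffeine,
    }
    conf_term = np.zeros(n_obs)
    for name in CONFOUNDS:
        beta = float(config.confound_effects.get(name, 0.0))
        conf_term += beta * (conf_vals[name] - _CONFOUND_CENTERS[name])

    sat = 1.0 - np.exp(-3.0 * maturation)
    hormones = {}
    for horm, (b_lin, b_sat) in config.hormone_slopes.items():
        base = 2.0 if horm == "dhea" else 1.5 + 0.8 * (sex_obs == "M")
        log_h = (
            base
            + b_lin * maturation
            + b_sat * sat
            + conf_term
            + rng.normal(0.0, config.hormone_noise_sd, size=n_obs)
        )
        hormones[horm] = np.exp(log_h)

    # --- BMI --------------------------------------------------------------
    bmi = (
        17.0
        + 0.6 * (age - 9.0)
        + 1.5 * (maturation - 0.5)
        + bmi_base[subj_idx]
        + rng.normal(0.0, 0.5, size=n_obs)
    )

    # --- outcome scales (T-score-like) ------------------------------------
    z_timing = timing / config.timing_sd if config.timing_sd > 0 else np.zeros(n_subj)
    eff = config.outcome_effect + config.outcome_effect_age_slope * (age - 11.0)
    resid_sd = config.outcome_sd * np.sqrt(max(0.0, 1.0 - config.outcome_effect**2))
    rho = config.outcome_corr
    g_subj = rng.normal(0.0, 1.0, size=n_subj)  # general-factor, shared across scales
    scores = {}
    for col in OUTCOME_COLUMNS + DSM_SCALES:
        site_b = (
            rng.normal(0.0, config.site_sd, size=config.n_sites)
            if config.site_sd > 0
            else np.zeros(config.n_sites)
        )
        e_obs = rng.normal(0.0, 1.0, size=n_obs)
        noise = resid_sd * (np.sqrt(rho) * g_subj[subj_idx] + np.sqrt(1.0 - rho) * e_obs)
        scores[col] = (
            50.0
            + config.outcome_sd * eff * z_timing[subj_idx]
            + site_b[site[subj_idx]]
            + noise
        )

    site_obs = site[subj_idx]
    df = pd.DataFrame(
        {
            "subject_id": [f"S{j:05d}" for j in subj_idx],
            "family_id": [f"F{family_of_subject[j]:05d}" for j in subj_idx],
            "site_id": [f"site{s:02d}" for s in site_obs],
            "wave": wave,
            "sex": sex_obs,
            "age": age,
            **pds,
            "menarche": menarche,
            "dhea": hormones["dhea"],
            "tst": hormones["tst"],
            **{k: conf_vals[k] for k in CONFOUNDS},
            "bmi": bmi,
            **scores,
            "race": [RACE_CATEGORIES[r] for r in race[subj_idx]],
            "ses_income": ses_income[subj_idx],
            "ses_education": ses_education[subj_idx],
            "truth_timing": timing[subj_idx],
            "truth_tempo": tempo[subj_idx],
            "truth_maturation": maturation,
        }
    )

    # --- MCAR missingness on measurement columns --------------------------
    if config.missing_rate > 0:
        maskable = (
            list(PDS_ITEMS) + ["dhea", "tst", "bmi"] + list(OUTCOME_COLUMNS) + list(DSM_SCALES)
        )
        for col in maskable:
            drop = rng.random(n_obs) < config.missing_rate
            df.loc[drop, col] = np.nan

    df.insert(0, "observation_id", df["subject_id"] + "_w" + df["wave"].astype(str))
    return df


#: documented column order of the cohort CSV
COHORT_COLUMNS = (
    ["observation_id", "subject_id", "family_id", "site_id", "wave", "sex", "age"]
    + list(PDS_ITEMS)
    + ["menarche", "dhea", "tst"]
    + list(CONFOUNDS)
    + ["bmi"]
    + list(OUTCOME_COLUMNS)
    + list(DSM_SCALES)
    + ["race", "ses_income", "ses_education"]
    + ["truth_timing", "truth_tempo", "truth_maturation"]
)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the documented column order."""
    df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    if isinstance(path, io.IOBase):
        return pd.read_csv(path)
    return pd.read_csv(path)
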