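"""Puberty-age-gap / mental-health association analysis.

For each sex x gap model x outcome scale, fits the linear mixed model

    outcome ~ gap + age + (1 | site)

by maximum likelihood (so AIC values are comparable across gap models with
identical fixed-effect structure), collects the gap coefficient, its Wald t
and p, and the model AIC; adjusts p-values with Benjamini-Hochberg FDR
within declared families; compares the three gap models per outcome with an
AIC cutoff of 2; and optionally tests a (mean-centered) gap x age
interaction and covariate-adjusted sensitivity models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pubertyage.lmm import fit_random_intercept
from pubertyage.simulate import OUTCOME_COLUMNS, RACE_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "fit_lmm",
    "fit_interaction_lmm",
    "bh_fdr",
    "compare_aic",
    "run_association_suite",
    "AssociationSuiteResult",
]


def _lmm_fit(y: np.ndarray, exog: np.ndarray, site: np.ndarray, names: list[str]):
    """ML mixed-model fit with a site random intercept; OLS if 1 site."""
    if np.var(y) == 0:
        raise ValueError("zero-variance outcome")
    n_sites = np.unique(site).size
    if n_sites < 2:
        logger.warning("single site: falling back to OLS (no random intercept)")
        res = sm.OLS(y, exog).fit()
        # normal-reference p-values, consistent with the mixed-model Wald test
        pvals = 2.0 * stats.norm.sf(np.abs(np.asarray(res.tvalues)))
        return res.params, res.tvalues, pvals, float(res.aic), res
    res = fit_random_intercept(y, exog, site)
    if not res.converged:
        logger.warning("mixed model did not converge (n=%d, %d sites)", y.size, n_sites)
    return res.params, res.tvalues, res.pvalues, res.aic, res


def _complete(arrs: list[np.ndarray]) -> np.ndarray:
    ok = np.ones(arrs[0].shape[0], bool)
    for a in arrs:
        if a.dtype.kind in "fc":
            ok &= np.isfinite(a)
        else:
            ok &= pd.notna(a)
    return ok


def fit_lmm(outcome, gap, age, site, covariates: pd.DataFrame | None = None) -> dict:
    """Fit ``outcome ~ gap + age (+ covariates) + (1|site)`` by ML.

    Returns a dict with the gap coefficient (outcome units per gap-year),
    its t statistic and Wald p, the ML AIC and the number of rows fitted.
    Complete cases only; a single-site input falls back to OLS with a
    warning.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(gap, float)
    a = np.asarray(age, float)
    s = np.asarray(site)
    cols = [g, a]
    names = ["gap", "age"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(c)
    ok = _complete([y, *cols]) & pd.notna(s)
    y, s = y[ok], s[ok]
    X = np.column_stack([np.ones(ok.sum())] + [c[ok] for c in cols])
    params, tvals, pvals, aic, res = _lmm_fit(y, X, s, ["const"] + names)
    i = 1  # gap column
    return {
        "coefficient": float(params[i]),
        "t": float(tvals[i]),
        "p": float(pvals[i]),
        "aic": aic,
        "n": int(ok.sum()),
        "converged": bool(getattr(res, "converged", True)),
    }


def fit_interaction_lmm(outcome, gap, age, site, covariates: pd.DataFrame | None = None) -> dict:
    """Add a mean-centered ``gap x age`` product term and test it.

    Centering both factors before multiplying decorrelates the product
    from the main effects, so the interaction t is invariant to shifting
    age or gap.  Returns the interaction coefficient, t and p (plus the
    main-effect results and AIC).
    """
    y = np.asarray(outcome, float)
    g = np.asarray(gap, float)
    a = np.asarray(age, float)
    s = np.asarray(site)
    cols = [g, a]
    names = ["gap", "age"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(float))
            names.append(c)
    ok = _complete([y, *cols]) & pd.notna(s)
    y, s = y[ok], s[ok]
    gc = g[ok] - g[ok].mean()
    ac = a[ok] - a[ok].mean()
    inter = gc * ac
    X = np.column_stack(
        [np.ones(ok.sum())] + [c[ok] for c in cols] + [inter]
    )
    params, tvals, pvals, aic, res = _lmm_fit(y, X, s, ["const"] + names + ["gap:age"])
    j = X.shape[1] - 1
    return {
        "coefficient": float(params[1]),
        "t": float(tvals[1]),
        "p": float(pvals[1]),
        "interaction_coefficient": float(params[j]),
        "interaction_t": float(tvals[j]),
        "interaction_p": float(pvals[j]),
        "aic": aic,
        "n": int(ok.sum()),
    }


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def compare_aic(aic_by_model: dict[str, float], n_by_model: dict[str, int] | None = None) -> dict:
    """AIC model comparison with the conventional cutoff of 2.

    The minimum-AIC model is flagged ``better`` only when its AIC is at
    least 2 units below every competitor; otherwise the models are
    ``indistinguishable``.  All pairwise deltas (relative to the best
    model) are reported.  If row counts are supplied, mismatched fitting
    sets are rejected.
    """
    if not aic_by_model:
        raise ValueError("need at least one AIC value")
    if n_by_model is not None and len(set(n_by_model.values())) > 1:
        raise ValueError(f"AICs come from different fitting sets: {n_by_model}")
    best = min(aic_by_model, key=aic_by_model.get)
    deltas = {m: aic_by_model[m] - aic_by_model[best] for m in aic_by_model}
    others = [d for m, d in deltas.items() if m != best]
    better = bool(all(d >= 2.0 for d in others)) if others else True
    return {
        "preferred": best,
        "better": better,
        "verdict": "better" if better else "indistinguishable",
        "deltas": deltas,
    }


def _covariate_frame(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand requested covariates into numeric model columns."""
    out = {}
    for cov in covariates:
        if cov in ("bmi", "bmi_z"):
            col = "bmi_z" if "bmi_z" in records.columns else "bmi"
            out["bmi_z"] = records[col].to_numpy(float)
        elif cov == "ses":
            out["ses_income"] = records["ses_income"].to_numpy(float)
            out["ses_education"] = records["ses_education"].to_numpy(float)
        elif cov == "race":
            # indicator contrasts against the largest category
            for cat in RACE_CATEGORIES[1:]:
                out[f"race_{cat}"] = (records["race"] == cat).astype(float).to_numpy()
        else:
            out[cov] = records[cov].to_numpy(float)
    return pd.DataFrame(out, index=records.index)


@dataclass
class AssociationSuiteResult:
    """Association-suite output: per-cell results and AIC comparisons."""

    table: pd.DataFrame
    aic_table: pd.DataFrame
    fdr_family: str
    q: float
    failures: list = field(default_factory=list)

    def report(self) -> str:
        lines = [
            f"Associations (FDR q = {self.q}, family = {self.fdr_family})",
            "",
            "  sex model      outcome              coef      t     p_fdr    AIC       n",
        ]
        for _, r in self.table.iterrows():
            star = "*" if r["p_fdr"] < self.q else " "
            lines.append(
                f"  {r['sex']}   {r['model']:<10} {r['outcome']:<20}"
                f"{r['coefficient']:>7.3f}{r['t']:>7.2f}  {r['p_fdr']:<8.3g}{r['aic']:<10.1f}{r['n']}{star}"
            )
        lines.append("")
        lines.append("  per-outcome AIC winner (cutoff 2)")
        for _, r in self.aic_table.iterrows():
            lines.append(
                f"  {r['sex']}  {r['outcome']:<20} -> {r['preferred']} ({r['verdict']})"
            )
        if self.failures:
            lines.append(f"  {len(self.failures)} fits failed: {self.failures}")
        return "\n".join(lines)

    def to_csv(self, prefix: str) -> None:
        self.table.to_csv(f"{prefix}_associations.csv", index=False)
        self.aic_table.to_csv(f"{prefix}_aic.csv", index=False)


def run_association_suite(
    gaps_by_model: dict[str, pd.DataFrame],
    records: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS,
    fdr_q: float = 0.05,
    fdr_family: str = "per-sex-model",
    interactions: bool = False,
    covariates: list[str] | None = None,
) -> AssociationSuiteResult:
    """Fit the full outcome x model x sex association grid.

    ``gaps_by_model`` maps each gap model name to its per-observation gap
    table; ``records`` is the family-stratified cohort (TD + non-TD)
    carrying the outcome scores and site ids.  Within each sex the three
    models are fitted on the common observation set so their AICs are
    comparable.  FDR adjustment is applied within each sex x model family
    across outcomes by default, or globally with ``fdr_family="global"``.
    """
    if fdr_family not in ("per-sex-model", "global"):
        raise ValueError("fdr_family must be 'per-sex-model' or 'global'")
    model_names = list(gaps_by_model)
    if not model_names:
        raise ValueError("no gap models supplied")
    rec = records.set_index("observation_id")
    rows = []
    failures: list[str] = []
    sexes = sorted({s for gf in gaps_by_model.values() for s in gf["sex"].unique()})
    for sex in sexes:
        per_model = {
            m: gf[gf["sex"] == sex].set_index("observation_id")
            for m, gf in gaps_by_model.items()
        }
        common = set.intersection(*(set(f.index) for f in per_model.values()))
        common &= set(rec.index)
        order = sorted(common)
        if not order:
            failures.append(f"no common observations for sex {sex}")
            continue
        sub = rec.loc[order]
        cov_frame = _covariate_frame(sub, covariates) if covariates else None
        for m in model_names:
            gaps = per_model[m].loc[order, "gap"]
            for out in outcomes:
                try:
                    fitfun = fit_interaction_lmm if interactions else fit_lmm
                    r = fitfun(
                        sub[out], gaps, sub["age"], sub["site_id"], covariates=cov_frame
                    )
                except Exception as exc:  # collect, keep going
                    failures.append(f"{sex}/{m}/{out}: {exc}")
                    continue
                row = {
                    "outcome": out,
                    "model": m,
                    "sex": sex,
                    "coefficient": r["coefficient"],
                    "t": r["t"],
                    "p_raw": r["p"],
                    "aic": r["aic"],
                    "n": r["n"],
                }
                if interactions:
                    row["interaction_t"] = r["interaction_t"]
                    row["interaction_p"] = r["interaction_p"]
                rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError(f"no association fits succeeded: {failures}")
    table["p_fdr"] = np.nan
    if fdr_family == "global":
        table["p_fdr"] = bh_fdr(table["p_raw"].to_numpy(), q=fdr_q)
    else:
        for (_, _), idx in table.groupby(["sex", "model"]).groups.items():
            table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p_raw"].to_numpy(), q=fdr_q)

    aic_rows = []
    for (sex, out), grp in table.groupby(["sex", "outcome"]):
        aics = dict(zip(grp["model"], grp["aic"]))
        ns = dict(zip(grp["model"], grp["n"]))
        cmp = compare_aic(aics, ns)
        aic_rows.append(
            {
                "sex": sex,
                "outcome": out,
                "preferred": cmp["preferred"],
                "verdict": cmp["verdict"],
                **{f"delta_{m}": d for m, d in cmp["deltas"].items()},
            }
        )
    return AssociationSuiteResult(
        table=table.reset_index(drop=True),
        aic_table=pd.DataFrame(aic_rows),
        fdr_family=fdr_family,
        q=fdr_q,
        failures=failures,
    )
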