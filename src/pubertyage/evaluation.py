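"""Model-performance metrics and paired comparisons.

Quantifies each puberty-age model by the Pearson correlation between
predicted and chronological age and the mean absolute error (MAE, years),
and compares models pairwise with a Wilcoxon signed-rank test on the paired
absolute prediction errors.

The signed-rank test computes its null distribution exactly (dynamic
programming over the doubled midranks, valid under ties) for up to 25
nonzero differences, and switches to the tie-corrected normal approximation
above.  Zero differences are dropped before ranking by default (Wilcoxon's
original treatment); ``zero_method="pratt"`` ranks them first and then
discards them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_r",
    "mae",
    "wilcoxon_signed_rank",
    "compare_models",
    "ComparisonResult",
    "EXACT_CUTOFF",
]

#: largest number of nonzero differences handled by exact enumeration
EXACT_CUTOFF = 25


def pearson_r(pred, age) -> float:
    """Product-moment correlation between predictions and age."""
    p = np.asarray(pred, float)
    a = np.asarray(age, float)
    if p.size != a.size:
        raise ValueError("pred and age must have equal length")
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(p) == 0 or np.var(a) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(stats.pearsonr(p, a).statistic)


def mae(pred, age) -> float:
    """Mean absolute error in years."""
    p = np.asarray(pred, float)
    a = np.asarray(age, float)
    if p.size != a.size:
        raise ValueError("pred and age must have equal length")
    if p.size < 1:
        raise ValueError("need at least 1 pair")
    return float(np.mean(np.abs(p - a)))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ via DP over doubled (integer) midranks."""
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in doubled:
        dp[r:] += dp[: total + 1 - r]
    n_pat = dp.sum()  # == 2**n
    w2 = int(round(2.0 * w_plus))
    p_le = dp[: w2 + 1].sum() / n_pat
    p_ge = dp[w2:].sum() / n_pat
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    err_a,
    err_b,
    zero_method: str = "wilcox",
) -> tuple[float, float]:
    """Paired signed-rank test on ``err_a - err_b``.

    Returns ``(W_plus, two_sided_p)`` where ``W_plus`` is the sum of the
    midranks of the positive differences.  Exact null distribution for up
    to 25 nonzero differences; tie-corrected normal approximation above.
    If every difference is zero the test is uninformative: returns
    ``(0.0, 1.0)`` with a warning rather than raising.
    """
    a = np.asarray(err_a, float)
    b = np.asarray(err_b, float)
    if a.size != b.size:
        raise ValueError("paired error vectors must have equal length")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"zero_method must be 'wilcox' or 'pratt', got {zero_method!r}")
    d = a - b
    if np.all(d == 0):
        logger.warning("all paired differences are zero; signed-rank p set to 1")
        return 0.0, 1.0

    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    else:  # pratt: rank zeros too, then discard their ranks
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_CUTOFF:
        p = _exact_signed_rank_p(ranks, w_plus)
        return w_plus, p

    # under the null each rank enters W+ independently with prob 1/2, so
    # mu = sum(r)/2 and var = sum(r^2)/4; with midranks this equals the
    # textbook n(n+1)(2n+1)/24 - sum(t^3 - t)/48 tie-corrected variance
    mu = ranks.sum() / 2.0
    sigma2 = float(np.sum(ranks**2)) / 4.0
    if sigma2 <= 0:
        return w_plus, 1.0
    z = (w_plus - mu) / np.sqrt(sigma2)
    return w_plus, float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ComparisonResult:
    """Per-model performance and pairwise signed-rank comparisons."""

    metrics: pd.DataFrame          # model, sex, n, r, mae
    tests: pd.DataFrame            # model_a, model_b, sex, n, statistic, p
    scope: str = "complete"        # "complete" (TD + non-TD) or "td"
    notes: list = field(default_factory=list)

    def report(self) -> str:
        lines = [f"Model comparison ({self.scope} sample)", ""]
        for sex in sorted(self.metrics["sex"].unique()):
            sub = self.metrics[self.metrics["sex"] == sex]
            lines.append(f"  sex = {sex}")
            lines.append("    model      n       r      MAE(yr)")
            for _, row in sub.iterrows():
                lines.append(
                    f"    {row['model']:<10}{row['n']:<8d}{row['r']:.3f}   {row['mae']:.3f}"
                )
            lines.append("")
        lines.append("  pairwise Wilcoxon signed-rank on absolute errors")
        lines.append("    pair                     sex   n       W+        p")
        for _, row in self.tests.iterrows():
            pair = f"{row['model_a']} vs {row['model_b']}"
            lines.append(
                f"    {pair:<25}{row['sex']:<6}{row['n']:<8d}{row['statistic']:<10.1f}{row['p']:.3g}"
            )
        return "\n".join(lines)

    def to_csv(self, prefix: str) -> None:
        self.metrics.to_csv(f"{prefix}_metrics.csv", index=False)
        self.tests.to_csv(f"{prefix}_tests.csv", index=False)


def compare_models(
    gap_results: dict[str, pd.DataFrame],
    td_only: bool = False,
    zero_method: str = "wilcox",
    use_corrected: bool = False,
) -> ComparisonResult:
    """Compare puberty-age models on an identical observation set.

    ``gap_results`` maps a model name to its per-observation gap table (as
    produced by :class:`~pubertyage.normative.PubertyAgeResults`).  All
    models must cover exactly the same observation ids per sex — mismatched
    sets are an error, never silently intersected.  Metrics are the
    correlation of predicted with chronological age and the MAE; all model
    pairs are compared with the signed-rank test on paired absolute errors.

    Performance is measured on the raw out-of-sample predictions by
    default.  The bias-corrected gap deliberately retains the pubertal
    timing signal — a model that captures timing *better* shows a *larger*
    corrected residual — so corrected gaps (``use_corrected=True``) gauge
    timing spread, not prediction accuracy.
    """
    if not gap_results:
        raise ValueError("no gap results supplied")
    frames = {}
    for name, gf in gap_results.items():
        f = gf[gf["fold"] != "nonTD"] if td_only else gf
        frames[name] = f.set_index("observation_id")

    metrics_rows, test_rows = [], []
    sexes = sorted({s for f in frames.values() for s in f["sex"].unique()})
    for sex in sexes:
        per_model = {name: f[f["sex"] == sex] for name, f in frames.items()}
        id_sets = {name: set(f.index) for name, f in per_model.items()}
        ref_name = next(iter(id_sets))
        for name, ids in id_sets.items():
            if ids != id_sets[ref_name]:
                diff = ids.symmetric_difference(id_sets[ref_name])
                raise ValueError(
                    f"models {ref_name!r} and {name!r} evaluated on different "
                    f"observation sets for sex {sex} ({len(diff)} ids differ)"
                )
        order = sorted(id_sets[ref_name])
        pred_col = "puberty_age" if use_corrected else "raw_prediction"
        for name, f in per_model.items():
            f = f.loc[order]
            metrics_rows.append(
                {
                    "model": name,
                    "sex": sex,
                    "n": len(f),
                    "r": pearson_r(f[pred_col], f["age"]),
                    "mae": mae(f[pred_col], f["age"]),
                }
            )
        for m_a, m_b in combinations(per_model, 2):
            fa = per_model[m_a].loc[order]
            fb = per_model[m_b].loc[order]
            ea = np.abs(fa[pred_col].to_numpy() - fa["age"].to_numpy())
            eb = np.abs(fb[pred_col].to_numpy() - fb["age"].to_numpy())
            w, p = wilcoxon_signed_rank(ea, eb, zero_method=zero_method)
            test_rows.append(
                {
                    "model_a": m_a,
                    "model_b": m_b,
                    "sex": sex,
                    "n": len(order),
                    "statistic": w,
                    "p": p,
                }
            )
    return ComparisonResult(
        metrics=pd.DataFrame(metrics_rows),
        tests=pd.DataFrame(test_rows),
        scope="td" if td_only else "complete",
    )
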