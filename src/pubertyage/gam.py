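"""Penalized-spline additive model for normative age prediction.

Fits ``age ~ b0 + sum_j f_j(x_j)`` where each ``f_j`` is a cubic penalized
B-spline.  Smoothing penalties are second-order *divided* differences of the
spline coefficients with respect to the Greville abscissae, so the penalty
null space is exactly the linear functions: as every ``lambda_j -> inf`` the
model collapses to the multiple linear regression on the same features.

Per-term penalties are tuned by minimizing the generalized cross-validation
score ``GCV = n * RSS / (n - edf)^2`` over a log-spaced grid, searched
coordinate-wise with a final local refinement pass.  The full grid trace is
retained on the results object.

Features with very few distinct values degrade gracefully: two or three
distinct values produce an (unpenalized) linear term, a constant feature is
demoted to a null term with a warning; four distinct values (ordinal PDS
items) get a single-interval cubic basis whose effective df is capped at 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = ["AdditiveAgeModel", "AdditiveAgeResults", "fit_gam", "default_penalty_grid"]


def default_penalty_grid(n_points: int = 7) -> np.ndarray:
    """Log-spaced smoothing-penalty grid on [1e-3, 1e3]."""
    return np.logspace(-3.0, 3.0, n_points)


@dataclass
class _Term:
    name: str
    kind: str                      # 'spline' | 'linear' | 'constant'
    sl: slice                      # columns in the full design
    knots: np.ndarray | None = None
    degree: int = 3
    col_means: np.ndarray | None = None
    Z: np.ndarray | None = None          # identifiability reparameterization
    penalty: np.ndarray | None = None    # Z' D'D Z for spline terms
    x_min: float = 0.0
    x_max: float = 1.0
    x_mean: float = 0.0


def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    k = degree
    n_basis = len(knots) - k - 1
    return np.array([knots[i + 1 : i + k + 1].mean() for i in range(n_basis)])


def _divided_diff_penalty(greville: np.ndarray) -> np.ndarray:
    """Second-order divided-difference matrix; null space = linear coefs."""
    g = greville
    m = len(g)
    D = np.zeros((m - 2, m))
    for i in range(m - 2):
        h1 = g[i + 1] - g[i]
        h2 = g[i + 2] - g[i + 1]
        D[i, i] = 1.0 / h1
        D[i, i + 1] = -(1.0 / h1 + 1.0 / h2)
        D[i, i + 2] = 1.0 / h2
    return D


def _spline_knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _basis_matrix(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return B


class AdditiveAgeModel:
    """Additive age-prediction model over a fixed feature matrix.

    Parameters
    ----------
    X : DataFrame or 2-D array
        Pubertal features (rows = observations).
    age : 1-D array-like
        Chronological age in years (the response).
    n_basis : int
        Target number of B-spline basis functions per smooth term; capped
        at the number of distinct feature values.
    """

    def __init__(self, X, age, n_basis: int = 10, degree: int = 3):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            self.feature_names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(age, float)
        if Xv.shape[0] != y.size:
            raise ValueError("X and age must have the same number of rows")
        if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(y))):
            raise ValueError("X and age must be finite (complete cases only)")
        self.X_raw = Xv
        self.age = y
        self.n = y.size
        self.degree = degree
        self.n_basis = n_basis
        self._build_design()

    # ------------------------------------------------------------------
    def _build_design(self) -> None:
        cols = [np.ones((self.n, 1))]
        self.terms: list[_Term] = []
        start = 1
        for j, name in enumerate(self.feature_names):
            x = self.X_raw[:, j]
            uniq = np.unique(x)
            lo, hi = float(x.min()), float(x.max())
            if uniq.size == 1:
                logger.warning("feature %r is constant; term demoted to null", name)
                self.terms.append(
                    _Term(name, "constant", slice(start, start), x_min=lo, x_max=hi,
                          x_mean=float(x.mean()))
                )
                continue
            if uniq.size <= 3:
                xc = (x - x.mean())[:, None]
                cols.append(xc)
                self.terms.append(
                    _Term(name, "linear", slice(start, start + 1),
                          x_min=lo, x_max=hi, x_mean=float(x.mean()))
                )
                start += 1
                continue
            k = max(self.degree + 1, min(self.n_basis, uniq.size))
            knots = _spline_knots(lo, hi, k, self.degree)
            B = _basis_matrix(x, knots, self.degree)
            mu = B.mean(axis=0)
            Bc = B - mu  # removes the constant direction (partition of unity)
            # the all-ones coefficient direction is now null in both design
            # and divided-difference penalty; drop it for identifiability
            Z = linalg.null_space(np.ones((1, k)))
            D = _divided_diff_penalty(_greville(knots, self.degree)) @ Z
            self.terms.append(
                _Term(name, "spline", slice(start, start + k - 1), knots, self.degree,
                      mu, Z, D.T @ D, lo, hi, float(x.mean()))
            )
            cols.append(Bc @ Z)
            start += k - 1
        self.design = np.hstack(cols)
        self.p = self.design.shape[1]
        self._G = self.design.T @ self.design
        self._Xty = self.design.T @ self.age
        self._yty = float(self.age @ self.age)
        self.smooth_terms = [t for t in self.terms if t.kind == "spline"]

    # ------------------------------------------------------------------
    def _pen_matrix(self, lambdas: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for t in self.smooth_terms:
            S[t.sl, t.sl] = lambdas[t.name] * t.penalty
        return S

    def _solve(self, lambdas: dict[str, float]):
        """Return (beta, rss, edf) at a fixed penalty vector."""
        S = self._pen_matrix(lambdas)
        A = self._G + S
        try:
            c, low = linalg.cho_factor(A, lower=True)
            beta = linalg.cho_solve((c, low), self._Xty)
            edf = float(np.trace(linalg.cho_solve((c, low), self._G)))
        except linalg.LinAlgError:
            # rank-deficient (e.g. perfectly collinear features): pinv solve
            Ainv = np.linalg.pinv(A, hermitian=True)
            beta = Ainv @ self._Xty
            edf = float(np.trace(Ainv @ self._G))
        rss = max(self._yty - 2.0 * beta @ self._Xty + beta @ self._G @ beta, 0.0)
        return beta, rss, edf

    def gcv(self, lambdas: dict[str, float]) -> float:
        """GCV = n * RSS / (n - edf)^2 at a fixed penalty vector."""
        _, rss, edf = self._solve(lambdas)
        denom = (self.n - edf) ** 2
        if denom <= 0:
            return np.inf
        return self.n * rss / denom

    # ------------------------------------------------------------------
    def fit(
        self,
        penalty_grid=None,
        n_passes: int = 2,
        refine: bool = True,
        exhaustive: bool = False,
    ) -> "AdditiveAgeResults":
        """Tune per-term penalties by GCV grid search and fit.

        Coordinate-wise sweeps over the grid (``n_passes`` rounds) followed
        by one local joint refinement on a half-step grid around the
        optimum; ``exhaustive=True`` evaluates the full Cartesian grid
        instead (cost grows exponentially in the number of smooth terms).
        """
        if self.n < 50:
            raise ValueError(f"need at least 50 rows to fit, got {self.n}")
        if not self.feature_names:
            raise ValueError("need at least one feature")
        grid = default_penalty_grid() if penalty_grid is None else np.asarray(penalty_grid, float)
        if grid.size == 0:
            raise ValueError("penalty grid must be non-empty")

        trace: list[tuple[dict, float]] = []

        def eval_point(lams: dict[str, float]) -> float:
            g = self.gcv(lams)
            if not np.isfinite(g):
                logger.info("non-finite GCV at %s; grid point skipped", lams)
                g = np.inf
            trace.append((dict(lams), g))
            return g

        names = [t.name for t in self.smooth_terms]
        if not names:
            lambdas: dict[str, float] = {}
            best_gcv = eval_point(lambdas)
        elif exhaustive:
            from itertools import product

            best_gcv, lambdas = np.inf, {nm: grid[len(grid) // 2] for nm in names}
            for combo in product(grid, repeat=len(names)):
                lams = dict(zip(names, map(float, combo)))
                g = eval_point(lams)
                if g < best_gcv:
                    best_gcv, lambdas = g, lams
        else:
            lambdas = {nm: float(grid[len(grid) // 2]) for nm in names}
            best_gcv = eval_point(lambdas)
            for _ in range(n_passes):
                for nm in names:
                    for lam in grid:
                        cand = dict(lambdas)
                        cand[nm] = float(lam)
                        g = eval_point(cand)
                        if g < best_gcv:
                            best_gcv, lambdas = g, cand
            if refine and len(grid) > 1:
                step = np.sqrt(grid[1] / grid[0])
                for nm in names:
                    for mult in (1.0 / step, step):
                        cand = dict(lambdas)
                        cand[nm] = lambdas[nm] * mult
                        g = eval_point(cand)
                        if g < best_gcv:
                            best_gcv, lambdas = g, cand

        beta, rss, edf = self._solve(lambdas)
        return AdditiveAgeResults(self, beta, dict(lambdas), best_gcv, rss, edf, trace)

    def fit_at(self, lambdas) -> "AdditiveAgeResults":
        """Fit at a fixed penalty value (scalar or per-term mapping)."""
        if np.isscalar(lambdas):
            lambdas = {t.name: float(lambdas) for t in self.smooth_terms}
        beta, rss, edf = self._solve(lambdas)
        denom = (self.n - edf) ** 2
        gcv = self.n * rss / denom if denom > 0 else np.inf
        return AdditiveAgeResults(self, beta, dict(lambdas), gcv, rss, edf, [])

    # ------------------------------------------------------------------
    def design_for(self, Xnew) -> np.ndarray:
        """Build the design matrix for new data using the training basis."""
        if isinstance(Xnew, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in Xnew.columns]
            if missing:
                raise ValueError(f"feature-set mismatch: missing columns {missing}")
            Xv = Xnew.loc[:, self.feature_names].to_numpy(float)
        else:
            Xv = np.asarray(Xnew, float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            if Xv.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"feature-set mismatch: expected {len(self.feature_names)} columns, "
                    f"got {Xv.shape[1]}"
                )
        n = Xv.shape[0]
        out = np.zeros((n, self.p))
        out[:, 0] = 1.0
        for j, t in enumerate(self.terms):
            x = Xv[:, self.feature_names.index(t.name)]
            if t.kind == "constant":
                continue
            if t.kind == "linear":
                out[:, t.sl] = (x - t.x_mean)[:, None]
            else:
                B = _basis_matrix(x, t.knots, t.degree)
                out[:, t.sl] = (B - t.col_means) @ t.Z
        return out


@dataclass
class AdditiveAgeResults:
    """A fitted additive age model with tuned penalties.

    Attributes
    ----------
    lambdas : per-smooth-term penalty chosen by GCV
    gcv_score : the minimized GCV value
    grid : the evaluated (penalty-vector, GCV) trace
    edf : effective degrees of freedom of the final fit
    """

    model: AdditiveAgeModel
    beta: np.ndarray
    lambdas: dict[str, float]
    gcv_score: float
    rss: float
    edf: float
    grid: list = field(default_factory=list)

    def predict(self, Xnew) -> np.ndarray:
        return self.model.design_for(Xnew) @ self.beta

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.design @ self.beta

    def partial_dependence(self, feature: str, n_grid: int = 50):
        """Marginal contribution ``f_j`` on an even grid over the feature range.

        Returns ``(grid, contribution)`` with the contribution centered to
        mean zero over the grid.  Feature importance can be summarized as
        ``contribution.max() - contribution.min()``.
        """
        names = [t.name for t in self.model.terms]
        if feature not in names:
            raise ValueError(f"unknown feature {feature!r}; have {names}")
        t = self.model.terms[names.index(feature)]
        xs = np.linspace(t.x_min, t.x_max, n_grid)
        if t.kind == "constant":
            f = np.zeros(n_grid)
        elif t.kind == "linear":
            f = (xs - t.x_mean) * self.beta[t.sl][0]
        else:
            B = (_basis_matrix(xs, t.knots, t.degree) - t.col_means) @ t.Z
            f = B @ self.beta[t.sl]
        return xs, f - f.mean()

    def feature_importance(self) -> dict[str, float]:
        """Range of each term's partial-dependence curve."""
        out = {}
        for t in self.model.terms:
            _, f = self.partial_dependence(t.name)
            out[t.name] = float(f.max() - f.min())
        return out

    def summary(self) -> str:
        lines = [
            "Additive age model",
            f"  n = {self.model.n}, edf = {self.edf:.2f}, GCV = {self.gcv_score:.5f}",
            f"  RSS = {self.rss:.4f}",
            "  term        kind      lambda     importance(yr)",
        ]
        imp = self.feature_importance()
        for t in self.model.terms:
            lam = self.lambdas.get(t.name, float("nan"))
            lines.append(f"  {t.name:<12}{t.kind:<10}{lam:<11.4g}{imp[t.name]:.3f}")
        return "\n".join(lines)


def fit_gam(features, age, penalty_grid=None, n_basis: int = 10, **kwargs) -> AdditiveAgeResults:
    """Convenience wrapper: build and tune an :class:`AdditiveAgeModel`."""
    return AdditiveAgeModel(features, age, n_basis=n_basis).fit(penalty_grid=penalty_grid, **kwargs)
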