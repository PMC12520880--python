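"""Radiomic feature selection: univariate test -> correlation pruning ->
LASSO with cross-validated penalty.

The cascade reduces a region feature table to the handful of features
entering a signature model:

1. **Univariate screen** — two-sided Mann-Whitney U per feature between
   outcome groups; keep p < alpha (0.05).  A one-way ANOVA screen is
   available as an option.
2. **Redundancy pruning** — greedy pass in ascending univariate-p order;
   a feature survives only if its Pearson |r| with every survivor so far
   is at or below the threshold (0.9), so each correlated group keeps its
   single most significant representative.
3. **LASSO** — squared-error lasso on the standardized survivors against
   the 0/1 outcome; the penalty is chosen by minimizing mean squared
   error over stratified, seeded 5-fold cross-validation on a
   logarithmic grid.  Nonzero-coefficient features define the radiomics
   score (radscore), a linear combination frozen at training time.

Missing rows (habitat regions below the minimum size) are mean-imputed
from the training data before the cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionReport",
    "univariate_filter",
    "correlation_prune",
    "lasso_select",
    "SelectionCascade",
]


@dataclass
class SelectionReport:
    """Per-stage record of the selection cascade."""

    input_features: list[str] = field(default_factory=list)
    univariate_p: dict[str, float] = field(default_factory=dict)
    after_univariate: list[str] = field(default_factory=list)
    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    after_pruning: list[str] = field(default_factory=list)
    lambda_grid: np.ndarray | None = None
    cv_mse: np.ndarray | None = None
    chosen_lambda: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    selected_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "input_features": self.input_features,
            "univariate_p": self.univariate_p,
            "after_univariate": self.after_univariate,
            "pruned_pairs": [[a, b, float(r)] for a, b, r in self.pruned_pairs],
            "after_pruning": self.after_pruning,
            "lambda_grid": None if self.lambda_grid is None else self.lambda_grid.tolist(),
            "cv_mse": None if self.cv_mse is None else self.cv_mse.tolist(),
            "chosen_lambda": self.chosen_lambda,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "selected_features": self.selected_features,
        }


# --------------------------------------------------------------------------
# stage 1: univariate screen
# --------------------------------------------------------------------------

def univariate_filter(table: pd.DataFrame, outcome: np.ndarray,
                      alpha: float = 0.05, method: str = "mannwhitney"
                      ) -> tuple[list[str], pd.Series]:
    """Per-feature two-group test; retain p < alpha.

    Constant features get p = 1 by convention and are dropped.  The
    Mann-Whitney p-value is exact for small tie-free samples and uses the
    tie-corrected normal approximation otherwise.
    """
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must have two nonempty groups")
    g0 = table.loc[y == 0]
    g1 = table.loc[y == 1]
    pvals = {}
    for col in table.columns:
        a = g0[col].to_numpy(dtype=float)
        b = g1[col].to_numpy(dtype=float)
        if np.nanstd(table[col].to_numpy(dtype=float)) == 0:
            pvals[col] = 1.0
            continue
        if method == "anova":
            _, p = stats.f_oneway(a, b)
        else:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="auto")
        pvals[col] = float(p) if np.isfinite(p) else 1.0
    pseries = pd.Series(pvals)
    kept = [c for c in table.columns if pseries[c] < alpha]
    return kept, pseries


# --------------------------------------------------------------------------
# stage 2: correlation pruning
# --------------------------------------------------------------------------

def correlation_prune(table: pd.DataFrame, p_values: pd.Series,
                      r_threshold: float = 0.9
                      ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy Pearson-correlation pruning in ascending-p order.

    Returns (kept features, dropped (feature, kept_representative, r)).
    Zero-variance features are excluded before pruning.
    """
    cols = [c for c in table.columns
            if np.std(table[c].to_numpy(dtype=float)) > 0]
    order = sorted(cols, key=lambda c: (p_values[c], cols.index(c)))
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    corr_cache = table[order].corr().abs()
    for c in order:
        conflict = None
        for k in kept:
            r = corr_cache.loc[c, k]
            if r > r_threshold:
                conflict = (k, float(r))
                break
        if conflict is None:
            kept.append(c)
        else:
            dropped.append((c, conflict[0], conflict[1]))
    return kept, dropped


# --------------------------------------------------------------------------
# stage 3: LASSO with CV-MSE penalty choice
# --------------------------------------------------------------------------

def lasso_select(table: pd.DataFrame, outcome: np.ndarray, folds: int = 5,
                 seed: int = 0, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-4
                 ) -> SelectionReport:
    """Squared-error lasso on the 0/1 outcome; lambda by stratified CV-MSE.

    The grid is logarithmic from the smallest lambda that zeroes every
    coefficient down by ``lambda_min_ratio``.  Features are z-scored on the
    full training table; coefficients are reported on that standardized
    scale, together with the intercept, defining
    radscore = intercept + sum(coef_i * z(feature_i)).
    """
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    if table.shape[1] < 1:
        raise ValueError("no features to select from")
    X = table.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    yc = y - y.mean()
    lam_max = np.max(np.abs(Z.T @ yc)) / n
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((folds, n_lambdas))
    for f, (tr, te) in enumerate(skf.split(Z, y)):
        Ztr, Zte = Z[tr], Z[te]
        ytr, yte = y[tr], y[te]
        for li, lam in enumerate(grid):
            model = Lasso(alpha=lam, max_iter=50_000)
            model.fit(Ztr, ytr)
            pred = model.predict(Zte)
            mse[f, li] = float(np.mean((yte - pred) ** 2))
    cv_mse = mse.mean(axis=0)
    best = int(np.argmin(cv_mse))
    lam = float(grid[best])
    final = Lasso(alpha=lam, max_iter=100_000)
    final.fit(Z, y)
    coefs = {c: float(w) for c, w in zip(table.columns, final.coef_)}
    selected = [c for c, w in coefs.items() if w != 0.0]
    report = SelectionReport(
        input_features=list(table.columns),
        lambda_grid=grid, cv_mse=cv_mse, chosen_lambda=lam,
        coefficients=coefs, intercept=float(final.intercept_),
        selected_features=selected,
    )
    return report


# --------------------------------------------------------------------------
# the full cascade as a transformer
# --------------------------------------------------------------------------

class SelectionCascade(BaseEstimator, TransformerMixin):
    """Univariate screen -> correlation pruning -> LASSO, as one fit.

    Parameters mirror the stage functions.  After ``fit``:

    * ``report_`` is the full :class:`SelectionReport`;
    * ``selected_features_`` the nonzero-coefficient columns;
    * ``transform`` returns the selected columns (imputed);
    * ``radscore`` maps a table to the linear radiomics score.
    """

    def __init__(self, alpha: float = 0.05, r_threshold: float = 0.9,
                 folds: int = 5, seed: int = 0, univariate: str = "mannwhitney",
                 n_lambdas: int = 100):
        self.alpha = alpha
        self.r_threshold = r_threshold
        self.folds = folds
        self.seed = seed
        self.univariate = univariate
        self.n_lambdas = n_lambdas

    def _impute(self, table: pd.DataFrame) -> pd.DataFrame:
        filled = table.copy()
        means = getattr(self, "impute_means_", None)
        if means is None:
            means = table.mean()
        return filled.fillna(means)

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("outcome y is required")
        y = np.asarray(y).astype(int)
        self.impute_means_ = X.mean()
        table = self._impute(X)
        report = SelectionReport(input_features=list(table.columns))

        kept, pvals = univariate_filter(table, y, alpha=self.alpha,
                                        method=self.univariate)
        report.univariate_p = {c: float(pvals[c]) for c in table.columns}
        report.after_univariate = kept
        if not kept:
            logger.warning("no feature passed the univariate screen")
            self.report_ = report
            self.selected_features_ = []
            return self

        pruned, dropped = correlation_prune(table[kept], pvals,
                                            r_threshold=self.r_threshold)
        report.pruned_pairs = dropped
        report.after_pruning = pruned
        if len(pruned) < 2:
            # lasso needs >= 2 features; a single survivor passes through
            report.selected_features = pruned
            report.coefficients = {c: 1.0 for c in pruned}
            report.intercept = 0.0
            self._scale = (table[pruned].mean(), table[pruned].std().replace(0, 1.0))
            self.report_ = report
            self.selected_features_ = pruned
            return self

        lasso_rep = lasso_select(table[pruned], y, folds=self.folds,
                                 seed=self.seed, n_lambdas=self.n_lambdas)
        report.lambda_grid = lasso_rep.lambda_grid
        report.cv_mse = lasso_rep.cv_mse
        report.chosen_lambda = lasso_rep.chosen_lambda
        report.coefficients = lasso_rep.coefficients
        report.intercept = lasso_rep.intercept
        report.selected_features = lasso_rep.selected_features
        self._scale = (table[pruned].mean(), table[pruned].std().replace(0, 1.0))
        self.report_ = report
        self.selected_features_ = lasso_rep.selected_features
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "report_")
        return self._impute(X)[self.selected_features_]

    def radscore(self, X: pd.DataFrame) -> np.ndarray:
        """Linear radiomics score from the lasso coefficients."""
        check_is_fitted(self, "report_")
        rep = self.report_
        if not rep.selected_features:
            return np.zeros(len(X))
        table = self._impute(X)
        mu, sd = self._scale
        score = np.full(len(X), rep.intercept or 0.0)
        for c in rep.selected_features:
            z = (table[c].to_numpy(dtype=float) - mu[c]) / sd[c]
            score = score + rep.coefficients[c] * z
        return score
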