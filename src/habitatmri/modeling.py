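"""Signature models, the combined nomogram and all evaluation surfaces.

Models
------
* :class:`SignatureClassifier` — logistic regression (maximum likelihood
  with a light L2 stabilizer) or a small single-hidden-layer MLP, both
  standardized and fully seeded; the decision threshold is the Youden
  optimum on the training ROC, frozen before any test evaluation.
* :class:`NomogramModel` — multivariate logistic on component scores
  (habitat radscore + clinicopathologic score), with the classical
  point-scale presentation: the component with the largest coefficient x
  observed-range product spans 0-100 points, others scale proportionally,
  and total points map monotonically to predicted probability.

Evaluation
----------
AUC is the Mann-Whitney pair statistic with half-credit for ties; its 95%
CI comes from the DeLong structural-component variance.  Threshold
metrics are the standard confusion rates.  Calibration is assessed by the
Hosmer-Lemeshow chi-square over risk deciles and a binned calibration
curve; clinical utility by decision-curve net benefit against treat-all /
treat-none.  A Table-1-style group-comparison summary (chi-squared and
Mann-Whitney tests) is provided for clinical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "split_cohort",
    "SignatureClassifier",
    "roc_auc",
    "delong_ci",
    "youden_threshold",
    "threshold_metrics",
    "hosmer_lemeshow",
    "calibration_curve_points",
    "decision_curve",
    "NomogramModel",
    "cohort_comparison_table",
    "EvalReport",
    "evaluate_scores",
    "CLINICAL_FEATURES",
]

#: default clinicopathologic covariate set (the superset of reported variants)
CLINICAL_FEATURES = ("age", "er", "pr", "her2", "ki67", "cT", "cN")


# --------------------------------------------------------------------------
# cohort splitting
# --------------------------------------------------------------------------

def split_cohort(ids, outcome, ratio: float = 0.8, seed: int = 0
                 ) -> tuple[list, list]:
    """Stratified random train/test split at *ratio* (train fraction).

    Disjoint and exhaustive; per-class train counts are round(n_c * ratio).
    """
    ids = list(ids)
    y = np.asarray(outcome).astype(int)
    if len(ids) != len(y):
        raise ValueError("ids and outcome length mismatch")
    if len(ids) < 10:
        raise ValueError("cohort too small to split")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(round(members.size * ratio))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [ids[i] for i in train_idx], [ids[i] for i in test_idx]


# --------------------------------------------------------------------------
# signature models
# --------------------------------------------------------------------------

class SignatureClassifier(BaseEstimator, ClassifierMixin):
    """Logistic-regression or MLP signature over selected features.

    Parameters
    ----------
    kind : {"logistic", "mlp"}
    hidden_units : int
        Hidden-layer width of the MLP (single hidden layer).
    l2 : float
        L2 stabilizer for the logistic fit (small; near-ML estimates).
    standardize : bool
        Z-score features inside the model (disable for coefficient
        recovery on a known generative scale).
    random_state : int

    After ``fit``: ``model_`` (the fitted sklearn estimator),
    ``threshold_`` (Youden-optimal on training scores), and for the
    logistic kind ``coef_`` / ``intercept_`` on the input scale.
    """

    def __init__(self, kind: str = "logistic", hidden_units: int = 16,
                 l2: float = 1e-4, standardize: bool = True,
                 max_iter: int = 5000, random_state: int = 0):
        self.kind = kind
        self.hidden_units = hidden_units
        self.l2 = l2
        self.standardize = standardize
        self.max_iter = max_iter
        self.random_state = random_state

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_") and list(X.columns) != self.feature_names_:
                raise ValueError("feature-name mismatch with fitted model")
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X[:, None] if X.ndim == 1 else X

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
        Xa = self._as_array(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both outcome classes to fit")
        if self.standardize:
            self.scaler_ = StandardScaler().fit(Xa)
            Z = self.scaler_.transform(Xa)
        else:
            self.scaler_ = None
            Z = Xa
        if self.kind == "logistic":
            n = len(y)
            model = LogisticRegression(
                penalty="l2", C=1.0 / (self.l2 * n), solver="lbfgs",
                max_iter=self.max_iter)
            model.fit(Z, y)
            if model.n_iter_[0] >= self.max_iter:
                raise RuntimeError(
                    f"logistic fit did not converge in {self.max_iter} iterations")
            coef = model.coef_[0].copy()
            intercept = float(model.intercept_[0])
            if self.scaler_ is not None:
                coef = coef / self.scaler_.scale_
                intercept -= float(np.sum(coef * self.scaler_.mean_))
            self.coef_, self.intercept_ = coef, intercept
        elif self.kind == "mlp":
            model = MLPClassifier(
                hidden_layer_sizes=(self.hidden_units,), activation="logistic",
                solver="adam", early_stopping=True, validation_fraction=0.2,
                max_iter=self.max_iter, random_state=self.random_state)
            model.fit(Z, y)
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        self.model_ = model
        self.classes_ = model.classes_
        self.threshold_ = youden_threshold(self.predict_proba(X)[:, 1], y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Z = self._as_array(X)
        if self.scaler_ is not None:
            Z = self.scaler_.transform(Z)
        return self.model_.predict_proba(Z)

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold_).astype(int)


# --------------------------------------------------------------------------
# ROC / AUC with DeLong CI
# --------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic (ties credit 0.5)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = _midranks(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def delong_ci(scores, labels, level: float = 0.95
              ) -> tuple[float, tuple[float, float]]:
    """AUC and its DeLong confidence interval.

    Variance from the structural components V10 (positives) and V01
    (negatives); the interval is clipped to [0, 1] and always contains the
    point estimate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc = roc_auc(s, y)
    all_ranks = _midranks(s)
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[y == 1] - pos_ranks) / n           # per-positive
    v01 = 1.0 - (all_ranks[y == 0] - neg_ranks) / m     # per-negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return auc, (float(lo), float(hi))


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = y.sum()
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    cand = np.unique(s)
    best_t, best_j = cand[0], -np.inf
    for t in cand:
        pred = s >= t
        sens = np.sum(pred & (y == 1)) / n1
        spec = np.sum(~pred & (y == 0)) / n0
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def threshold_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV at a fixed threshold.

    Positive class is the event (pCR).  Undefined predictive values (no
    predicted positives/negatives) are reported as NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    out = {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }
    if tp + fp == 0:
        logger.warning("no predicted positives; PPV undefined")
    if tn + fn == 0:
        logger.warning("no predicted negatives; NPV undefined")
    return out


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def hosmer_lemeshow(probs, labels, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-calibration test over risk groups.

    chi2 = sum_g (O_g - E_g)^2 / (n_g * ebar_g * (1 - ebar_g)) with
    groups formed as deciles of predicted risk (tie-heavy deciles merged);
    p from chi2 with (groups - 2) degrees of freedom.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if len(p) < groups:
        raise ValueError("fewer observations than groups")
    q = pd.qcut(p, groups, duplicates="drop")
    g = q.codes
    n_groups = g.max() + 1
    if n_groups < groups:
        logger.info("tie-heavy deciles merged: %d -> %d groups", groups, n_groups)
    if n_groups < 2:
        raise ValueError("too few distinct risk groups after merging")
    chi2 = 0.0
    for k in range(n_groups):
        sel = g == k
        n_k = int(sel.sum())
        obs = float(y[sel].sum())
        ebar = float(p[sel].mean())
        exp = n_k * ebar
        denom = n_k * ebar * (1.0 - ebar)
        if denom <= 0:
            continue
        chi2 += (obs - exp) ** 2 / denom
    df = max(n_groups - 2, 1)
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), pval


def calibration_curve_points(probs, labels, bins: int = 10) -> pd.DataFrame:
    """Binned (predicted, observed) calibration pairs."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    q = pd.qcut(p, bins, duplicates="drop")
    df = pd.DataFrame({"p": p, "y": y, "bin": q.codes})
    out = df.groupby("bin").agg(predicted=("p", "mean"),
                                observed=("y", "mean"),
                                n=("y", "size")).reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# decision-curve analysis
# --------------------------------------------------------------------------

def decision_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none.

    NB(pt) = TP/n - FP/n * pt/(1-pt); treat-all has TP = all positives,
    FP = all negatives.  Thresholds at or above 1 are excluded.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    pi = y.mean()
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray([t for t in np.atleast_1d(thresholds)
                             if 0 < t < 1], dtype=float)
    rows = []
    for pt in thresholds:
        w = pt / (1 - pt)
        pred = p >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * w,
            "treat_all": pi - (1 - pi) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# nomogram
# --------------------------------------------------------------------------

class NomogramModel(BaseEstimator):
    """Multivariate logistic combination of component scores with the
    classical point-scale presentation.

    Fit on a DataFrame of component scores (e.g. habitat radscore and
    clinicopathologic score).  The component with the largest
    |coefficient| x observed-range spans 0-100 points; other components
    scale proportionally.  Total points map monotonically to predicted
    probability.
    """

    def __init__(self, l2: float = 1e-4, max_iter: int = 5000):
        self.l2 = l2
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        if (X.std(axis=0) == 0).any():
            bad = X.columns[(X.std(axis=0) == 0)].tolist()
            raise ValueError(f"degenerate (zero variance) components: {bad}")
        self.components_ = list(X.columns)
        base = SignatureClassifier(kind="logistic", l2=self.l2,
                                   standardize=True, max_iter=self.max_iter)
        base.fit(X, y)
        self.model_ = base
        self.coef_ = dict(zip(self.components_, base.coef_))
        self.intercept_ = base.intercept_
        # point scales: affine per component, anchored at the value
        # minimizing the linear predictor contribution
        self.ranges_ = {c: (float(X[c].min()), float(X[c].max()))
                        for c in self.components_}
        spans = {c: abs(self.coef_[c]) * (self.ranges_[c][1] - self.ranges_[c][0])
                 for c in self.components_}
        ref = max(spans.values())
        if ref == 0:
            raise ValueError("all components have zero effect; nomogram undefined")
        self.points_per_lp_ = 100.0 / ref
        return self

    def _component_lp(self, c: str, x: np.ndarray) -> np.ndarray:
        b = self.coef_[c]
        lo, hi = self.ranges_[c]
        anchor = lo if b >= 0 else hi  # zero points at the least-risk end
        return b * (np.asarray(x, dtype=float) - anchor)

    def points_for(self, c: str, x) -> np.ndarray:
        """Points contributed by component *c* at value(s) *x*."""
        check_is_fitted(self, "model_")
        return self._component_lp(c, x) * self.points_per_lp_

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        return sum(self.points_for(c, X[c]) for c in self.components_)

    def probability_for_total_points(self, points) -> np.ndarray:
        """Monotone map from total points to predicted probability."""
        check_is_fitted(self, "model_")
        offset = self.intercept_ + sum(
            self.coef_[c] * (self.ranges_[c][0] if self.coef_[c] >= 0
                             else self.ranges_[c][1])
            for c in self.components_)
        lp = offset + np.asarray(points, dtype=float) / self.points_per_lp_
        return 1.0 / (1.0 + np.exp(-lp))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict_proba(X)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.decision_scores(X)

    @property
    def threshold_(self) -> float:
        return self.model_.threshold_


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Threshold metrics, AUC + CI, calibration and DCA for one model/cohort."""

    name: str
    cohort: str
    n: int
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    metrics: dict[str, float]
    hl_chi2: float | None = None
    hl_p: float | None = None
    calibration: pd.DataFrame | None = None
    dca: pd.DataFrame | None = None

    def summary_row(self) -> dict:
        return {
            "model": self.name, "cohort": self.cohort, "n": self.n,
            "accuracy": self.metrics["accuracy"], "auc": self.auc,
            "ci_low": self.auc_ci[0], "ci_high": self.auc_ci[1],
            "sensitivity": self.metrics["sensitivity"],
            "specificity": self.metrics["specificity"],
            "ppv": self.metrics["ppv"], "npv": self.metrics["npv"],
            "hl_chi2": self.hl_chi2, "hl_p": self.hl_p,
        }


def evaluate_scores(name: str, cohort: str, scores, labels, threshold: float,
                    with_calibration: bool = True) -> EvalReport:
    """Full evaluation of per-patient scores against binary labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc, ci = delong_ci(s, y)
    metrics = threshold_metrics(s, y, threshold)
    hl_chi2 = hl_p = None
    calib = None
    probs_like = np.all((s >= 0) & (s <= 1))
    if with_calibration and probs_like and len(y) >= 30:
        try:
            hl_chi2, hl_p = hosmer_lemeshow(s, y, groups=min(10, len(y) // 5))
            calib = calibration_curve_points(s, y, bins=min(10, len(y) // 5))
        except ValueError:
            logger.info("calibration skipped for %s/%s (degenerate groups)",
                        name, cohort)
    dca = decision_curve(s, y) if probs_like else None
    return EvalReport(name=name, cohort=cohort, n=len(y), auc=auc, auc_ci=ci,
                      threshold=threshold, metrics=metrics,
                      hl_chi2=hl_chi2, hl_p=hl_p, calibration=calib, dca=dca)


# --------------------------------------------------------------------------
# Table-1-style cohort comparison
# --------------------------------------------------------------------------

_CATEGORICAL = {
    "menopause": {0: "Premenopause", 1: "Post-menopause"},
    "er": {0: "Negative", 1: "Positive"},
    "pr": {0: "Negative", 1: "Positive"},
    "her2": {0: "Negative", 1: "Positive"},
    "cT": {1: "T1", 2: "T2", 3: "T3", 4: "T4"},
    "cN": {1: "N1", 2: "N2"},
}
_CONTINUOUS = ("age", "ki67")


def cohort_comparison_table(clinical: pd.DataFrame, outcome=None
                            ) -> pd.DataFrame:
    """Group summaries by outcome with chi-squared / Mann-Whitney tests.

    Categorical rows report "count (percent%)" with percentages computed
    within each outcome group and rounded to 2 decimals; continuous rows
    report "median (q1, q3)".  Chi-squared tests are flagged unreliable
    when any expected cell count is below 1.
    """
    df = clinical.copy()
    if outcome is not None:
        df = df.assign(pcr=np.asarray(outcome).astype(int))
    if "pcr" not in df.columns:
        raise ValueError("no outcome column")
    y = df["pcr"].astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 patients per outcome group")
    g0, g1 = df[y == 0], df[y == 1]
    rows = []
    for var, levels in _CATEGORICAL.items():
        if var not in df.columns:
            continue
        table = np.array([
            [(g[var] == code).sum() for g in (g0, g1)]
            for code in levels
        ], dtype=float)
        keep = table.sum(axis=1) > 0
        note = ""
        if keep.sum() >= 2:
            chi2, p, _, expected = stats.chi2_contingency(table[keep])
            if (expected < 1).any():
                note = "unreliable (low expected counts)"
                logger.warning("chi-squared unreliable for %s", var)
        else:
            p = 1.0
        rows.append({"variable": var, "level": "", "non_pCR": "", "pCR": "",
                     "p_value": round(float(p), 4), "test": "chi-squared",
                     "note": note})
        for (code, label), (c0, c1) in zip(levels.items(), table):
            pct0 = round(100 * c0 / len(g0), 2)
            pct1 = round(100 * c1 / len(g1), 2)
            rows.append({"variable": var, "level": label,
                         "non_pCR": f"{int(c0)} ({pct0:.2f}%)",
                         "pCR": f"{int(c1)} ({pct1:.2f}%)",
                         "p_value": np.nan, "test": "", "note": ""})
    for var in _CONTINUOUS:
        if var not in df.columns:
            continue
        a = g0[var].to_numpy(dtype=float)
        b = g1[var].to_numpy(dtype=float)
        if np.std(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        fmt = lambda v: (f"{np.median(v):.0f} ({np.percentile(v, 25):.0f}, "
                         f"{np.percentile(v, 75):.0f})")
        rows.append({"variable": var, "level": "", "non_pCR": fmt(a),
                     "pCR": fmt(b), "p_value": round(float(p), 4),
                     "test": "mann-whitney", "note": ""})
    return pd.DataFrame(rows)
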