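"""Evaluation statistics: AUC/DeLong, threshold metrics, calibration,
decision curves, the nomogram and the clinical comparison table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from habitatmri.modeling import (
    NomogramModel,
    SignatureClassifier,
    cohort_comparison_table,
    decision_curve,
    delong_ci,
    evaluate_scores,
    hosmer_lemeshow,
    roc_auc,
    split_cohort,
    threshold_metrics,
    youden_threshold,
)
from habitatmri.synthetic import simulate_logistic_cohort


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half-credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

class TestSplitCohort:
    def test_stratified_80_20(self):
        y = np.array([0] * 60 + [1] * 40)
        tr, te = split_cohort(list(range(100)), y, ratio=0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20
        assert sum(y[i] for i in tr) == 32  # class proportions preserved
        assert sorted(tr + te) == list(range(100))

    def test_same_seed_reproduces(self):
        y = np.array([0, 1] * 20)
        assert split_cohort(list(range(40)), y, seed=7) == \
               split_cohort(list(range(40)), y, seed=7)

    @pytest.mark.parametrize("seed", range(50))
    def test_disjoint_exhaustive_sweep(self, seed):
        y = (np.arange(37) % 3 == 0).astype(int)
        tr, te = split_cohort(list(range(37)), y, seed=seed)
        assert set(tr) | set(te) == set(range(37))
        assert set(tr) & set(te) == set()

    def test_tiny_class_rejected(self):
        y = np.array([0] * 11 + [1])
        with pytest.raises(ValueError):
            split_cohort(list(range(12)), y)


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

class TestAuc:
    def test_worked_example(self):
        # 3 of 4 pairs concordant
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 8, [0, 1] * 4) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        assert roc_auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestDelongCi:
    def test_interval_contains_point(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s = rng.normal(size=80) + 0.8 * y
        auc, (lo, hi) = delong_ci(s, y)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_coverage_near_nominal(self):
        """CI covers the true AUC close to nominally over repeated draws
        (true DeLong coverage at this AUC and n is ~92-93%)."""
        from scipy.stats import norm
        mu = 1.0
        true_auc = float(norm.cdf(mu / np.sqrt(2)))  # binormal equal-variance
        hits = 0
        reps = 1000
        for r in range(reps):
            rng = np.random.default_rng(r)
            y = np.array([0] * 250 + [1] * 250)
            s = rng.normal(size=500) + mu * y
            _, (lo, hi) = delong_ci(s, y)
            hits += lo <= true_auc <= hi
        assert 0.91 <= hits / reps <= 0.98


# --------------------------------------------------------------------------
# threshold metrics
# --------------------------------------------------------------------------

class TestThresholdMetrics:
    def test_confusion_rates(self):
        # 79 TP, 21 FN, 82 TN, 18 FP
        scores = np.concatenate([np.ones(79), np.zeros(21), np.zeros(82),
                                 np.ones(18)])
        labels = np.concatenate([np.ones(100), np.zeros(100)]).astype(int)
        m = threshold_metrics(scores, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(0.79)
        assert m["specificity"] == pytest.approx(0.82)

    def test_threshold_below_all(self):
        m = threshold_metrics([0.2, 0.6, 0.9], [0, 1, 1], -1.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_threshold_above_all(self):
        m = threshold_metrics([0.2, 0.6, 0.9], [0, 1, 1], 2.0)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0
        assert np.isnan(m["ppv"])

    def test_youden_maximizes_j(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.normal(size=60) + y
        t = youden_threshold(s, y)
        j_at = lambda th: (threshold_metrics(s, y, th)["sensitivity"]
                           + threshold_metrics(s, y, th)["specificity"])
        assert all(j_at(t) >= j_at(c) - 1e-12 for c in np.unique(s))


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

class TestHosmerLemeshow:
    def test_two_group_hand_example(self):
        # groups of 4 with observed (1, 3) and constant risks (0.5, 0.5):
        # chi2 = (1-2)^2/(4*.25) + (3-2)^2/(4*.25) = 2
        probs = np.array([0.3] * 4 + [0.7] * 4)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        chi2, p = hosmer_lemeshow(probs, y, groups=2)
        e1, e2 = 4 * 0.3, 4 * 0.7
        expect = (1 - e1) ** 2 / (4 * 0.3 * 0.7) + (3 - e2) ** 2 / (4 * 0.7 * 0.3)
        assert chi2 == pytest.approx(expect, abs=1e-12)

    def test_perfectly_calibrated_groups(self):
        # risks equal to the empirical group rates -> chi2 0
        probs = np.array([0.25] * 4 + [0.75] * 4)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        chi2, p = hosmer_lemeshow(probs, y, groups=2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_well_specified_model_rejects_rarely(self):
        """Fitted well-specified logistic: HL rejects at ~nominal rate."""
        rejections = 0
        for seed in range(50):
            X, y = simulate_logistic_cohort(2000, [1.0, -0.5], -0.3, seed=seed)
            clf = SignatureClassifier(kind="logistic",
                                      standardize=False).fit(X, y)
            probs = clf.predict_proba(X)[:, 1]
            _, p = hosmer_lemeshow(probs, y)
            rejections += p < 0.05
        assert rejections <= 5  # <= 10% of seeds

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.2, 0.4, 0.6], [0, 1, 0], groups=1)


class TestDecisionCurve:
    def test_treat_all_matches_closed_form(self):
        y = np.array([1] * 40 + [0] * 60)
        probs = np.linspace(0.01, 0.99, 100)
        df = decision_curve(probs, y, thresholds=np.arange(0.05, 1.0, 0.05))
        pi = 0.4
        expect = pi - (1 - pi) * df["threshold"] / (1 - df["threshold"])
        assert np.allclose(df["treat_all"], expect, atol=1e-12)

    def test_treat_all_limit_is_prevalence(self):
        y = np.array([1] * 4 + [0] * 6)
        df = decision_curve(np.linspace(0, 1, 10), y, thresholds=[1e-9])
        assert df["treat_all"].iloc[0] == pytest.approx(0.4, abs=1e-6)

    def test_perfect_predictor_net_benefit(self):
        y = np.array([1] * 30 + [0] * 70)
        probs = y.astype(float)
        df = decision_curve(probs, y, thresholds=np.arange(0.1, 1.0, 0.1))
        assert np.allclose(df["net_benefit"], 0.3, atol=1e-12)

    def test_example_prevalence_04(self):
        # treat-all at pt = 0.25, prevalence 0.4: NB = 0.4 - 0.6/3 = 0.2
        y = np.array([1] * 4 + [0] * 6)
        df = decision_curve(np.ones(10), y, thresholds=[0.25])
        assert df["net_benefit"].iloc[0] == pytest.approx(0.2, abs=1e-12)

    def test_no_classifier_beats_perfect(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        probs = np.clip(rng.normal(0.5, 0.3, 200), 0, 1)
        grid = np.arange(0.05, 1.0, 0.05)
        df = decision_curve(probs, y, grid)
        perfect = decision_curve(y.astype(float), y, grid)
        assert np.all(df["net_benefit"] <= perfect["net_benefit"] + 1e-12)


# --------------------------------------------------------------------------
# signature models
# --------------------------------------------------------------------------

class TestSignatureClassifier:
    def test_separable_toy_auc_one(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        clf = SignatureClassifier(kind="logistic").fit(X, y)
        assert roc_auc(clf.decision_scores(X), y) == 1.0

    def test_logistic_coefficient_recovery(self):
        """ML fit recovers generating coefficients within 10% at n=5000."""
        coefs = np.array([0.8, -0.6, 0.4])
        X, y = simulate_logistic_cohort(5000, coefs, intercept=-0.3, seed=4)
        clf = SignatureClassifier(kind="logistic", standardize=False).fit(X, y)
        assert np.all(np.abs(clf.coef_ - coefs) <= 0.1 * np.abs(coefs))
        assert abs(clf.intercept_ - (-0.3)) <= 0.1 * 0.3 + 0.05

    def test_permuted_labels_give_null_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = simulate_logistic_cohort(300, [1.0, 0.5], 0.0, seed=seed)
            yp = rng.permutation(y)
            tr, te = slice(0, 200), slice(200, 300)
            clf = SignatureClassifier(kind="logistic").fit(X[tr], yp[tr])
            aucs.append(roc_auc(clf.decision_scores(X[te]), yp[te]))
        assert abs(np.mean(aucs) - 0.5) <= 0.07

    def test_mlp_seeded_and_probabilistic(self):
        X, y = simulate_logistic_cohort(200, [1.5], 0.0, seed=1)
        a = SignatureClassifier(kind="mlp", random_state=3).fit(X, y)
        b = SignatureClassifier(kind="mlp", random_state=3).fit(X, y)
        pa, pb = a.decision_scores(X), b.decision_scores(X)
        assert np.allclose(pa, pb)
        assert np.all((pa >= 0) & (pa <= 1))


# --------------------------------------------------------------------------
# nomogram
# --------------------------------------------------------------------------

class TestNomogram:
    def _components(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        rad = rng.normal(size=n)
        clin = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 * rad + 0.8 * clin)).astype(int)
        return pd.DataFrame({"radscore": rad, "clinical_score": clin}), y

    def test_zero_weight_component_matches_single_predictor(self):
        rng = np.random.default_rng(1)
        rad = rng.normal(size=300)
        y = (rng.random(300) < expit(2.0 * rad)).astype(int)
        X = pd.DataFrame({"radscore": rad,
                          "clinical_score": rng.normal(size=300)})
        nomo = NomogramModel().fit(X, y)
        solo = SignatureClassifier(kind="logistic").fit(
            pd.DataFrame({"radscore": rad}), y)
        # the irrelevant component's coefficient is near zero, so the
        # predicted risks track the single-predictor model closely
        assert np.corrcoef(nomo.decision_scores(X),
                           solo.decision_scores(X[["radscore"]]))[0, 1] > 0.99

    def test_total_points_probability_monotone(self):
        X, y = self._components()
        nomo = NomogramModel().fit(X, y)
        pts = np.linspace(-50, 250, 60)
        probs = nomo.probability_for_total_points(pts)
        assert np.all(np.diff(probs) >= 0)

    def test_point_scale_spans_100(self):
        X, y = self._components()
        nomo = NomogramModel().fit(X, y)
        spans = [abs(nomo.points_for(c, X[c].max())
                     - nomo.points_for(c, X[c].min()))
                 for c in nomo.components_]
        assert max(spans) == pytest.approx(100.0)

    def test_total_points_map_consistent_with_model(self):
        X, y = self._components(seed=3)
        nomo = NomogramModel().fit(X, y)
        via_points = nomo.probability_for_total_points(nomo.total_points(X))
        direct = nomo.predict_proba(X)[:, 1]
        assert np.allclose(via_points, direct, atol=1e-9)

    def test_degenerate_component_rejected(self):
        X = pd.DataFrame({"radscore": [1, 2, 3, 4], "flat": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="degenerate"):
            NomogramModel().fit(X, [0, 1, 0, 1])


# --------------------------------------------------------------------------
# Table-1-style comparison
# --------------------------------------------------------------------------

def _clinical_from_counts():
    """Rebuild a patient table from published contingency counts."""
    rows = []
    # non-pCR: 107 patients, 29 ER-, 22 Her2+; pCR: 82, 47 ER-, 59 Her2+
    for pcr, n, er_neg, her2_pos in ((0, 107, 29, 22), (1, 82, 47, 59)):
        for i in range(n):
            rows.append({
                "er": 0 if i < er_neg else 1,
                "her2": 1 if i < her2_pos else 0,
                "pcr": pcr,
            })
    return pd.DataFrame(rows)


class TestComparisonTable:
    def test_reported_percentages_reproduced(self):
        df = _clinical_from_counts()
        table = cohort_comparison_table(df[["er", "her2"]], df["pcr"])
        er_neg = table[(table.variable == "er") & (table.level == "Negative")]
        assert er_neg["non_pCR"].iloc[0] == "29 (27.10%)"
        assert er_neg["pCR"].iloc[0] == "47 (57.32%)"
        her2_pos = table[(table.variable == "her2") & (table.level == "Positive")]
        assert her2_pos["non_pCR"].iloc[0] == "22 (20.56%)"
        assert her2_pos["pCR"].iloc[0] == "59 (71.95%)"

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({
            "er": [0, 1] * 20,
            "pcr": [0] * 20 + [1] * 20,
        })
        table = cohort_comparison_table(df[["er"]], df["pcr"])
        p = table[table.variable == "er"]["p_value"].iloc[0]
        assert p == pytest.approx(1.0)

    def test_associated_variable_detected(self):
        df = _clinical_from_counts()
        table = cohort_comparison_table(df[["er"]], df["pcr"])
        assert table[table.variable == "er"]["p_value"].iloc[0] < 0.05


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------

def test_evaluate_scores_assembles_report(rng):
    y = rng.integers(0, 2, 120)
    y[:2] = [0, 1]
    probs = np.clip(expit(rng.normal(size=120) + y), 1e-6, 1 - 1e-6)
    rep = evaluate_scores("m", "train", probs, y, threshold=0.5)
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
    assert all(0 <= rep.metrics[k] <= 1 for k in
               ("accuracy", "sensitivity", "specificity"))
    assert rep.dca is not None and rep.hl_chi2 is not None
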