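"""ROC/Youden/bootstrap/confusion/correlation machinery against
independent oracles (brute-force pair counting, exhaustive threshold
search, closed-form AUC, sklearn)."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from scintira.cohort import truncated_normal
from scintira.diagnostics import (
    bootstrap_auc_ci,
    compare_groups,
    confusion_metrics,
    pearson_correlation,
    predictive_values_from_rates,
    roc_auc,
    youden_cutoff,
)
from scintira.errors import AnalysisError


def brute_force_auc(scores, labels):
    """Pair-counting oracle: concordant pairs + half ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive threshold enumeration with the documented tie rule:
    max J, then higher sensitivity, then lower threshold."""
    pos = np.array([s for s, y in zip(scores, labels) if y], dtype=float)
    neg = np.array([s for s, y in zip(scores, labels) if not y], dtype=float)
    best = None
    for c in [np.inf] + sorted(set(scores), reverse=True):
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), sens, -c)
        if best is None or key > best[0]:
            best = (key, (c, sens, spec))
    return best[1]


class TestRocAuc:
    def test_small_example_three_of_four_pairs_concordant(self):
        assert roc_auc([1, 2, 3, 4], [False, True, False, True]).auc == 0.75

    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 5.0, 6.0], [False, False, True, True])
        assert roc.auc == 1.0

    def test_all_ties_is_chance(self):
        assert roc_auc([2.0] * 6, [True, False] * 3).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(0)
        roc = roc_auc(rng.normal(size=60), rng.random(60) > 0.5)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)
        assert np.all(np.diff(roc.thresholds) < 0)

    def test_trapezoid_equals_pair_counting_oracle_exactly(self):
        """Oracle equivalence on random tied instances with n <= 50."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 51)
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.random(n) > 0.5
            if labels.all() or not labels.any():
                continue
            ours = roc_auc(scores, labels).auc
            assert ours == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestYouden:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 41)
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.random(n) > 0.4
            if labels.all() or not labels.any():
                continue
            got = youden_cutoff(roc_auc(scores, labels))
            expected = brute_force_youden(scores, labels)
            assert got == pytest.approx(expected)

    def test_tie_breaks_toward_higher_sensitivity(self):
        cutoff, sens, spec = youden_cutoff(
            roc_auc([1, 2, 3, 4], [False, True, False, True])
        )
        # J = 0.5 at cutoffs 2 and 4; higher sensitivity wins
        assert (cutoff, sens, spec) == (2.0, 1.0, 0.5)

    def test_perfect_separation_attains_j_of_one(self):
        cutoff, sens, spec = youden_cutoff(
            roc_auc([0.1, 0.2, 5.0, 6.0], [False, False, True, True])
        )
        assert sens + spec - 1.0 == 1.0
        assert cutoff == 5.0  # lowest threshold achieving J = 1

    def test_uptake_mixture_cutoff_matches_density_crossing(self):
        """For continuous groups the Youden-optimal threshold sits where the
        positive and negative densities cross; the empirical cut-off for the
        status-conditional ratio mixture must converge to that point."""
        from scipy.optimize import brentq

        def f_neg(c):
            return sps.norm.pdf(c, 1.12, 0.49)

        def f_pos(c):
            w = np.array([174, 44, 200]) / 418
            comps = [sps.norm.pdf(c, 1.68, 0.81), sps.norm.pdf(c, 2.07, 0.92),
                     sps.norm.pdf(c, 1.94, 1.16)]
            return float(w @ comps)

        crossing = brentq(lambda c: f_pos(c) - f_neg(c), 1.2, 2.5)
        cutoffs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            neg = truncated_normal(rng, 1.12, 0.49, 0.05, 1399)
            pos = np.concatenate([
                truncated_normal(rng, 1.68, 0.81, 0.05, 174),
                truncated_normal(rng, 2.07, 0.92, 0.05, 44),
                truncated_normal(rng, 1.94, 1.16, 0.05, 200),
            ])
            scores = np.concatenate([neg, pos])
            labels = np.r_[np.zeros(1399, bool), np.ones(418, bool)]
            cutoffs.append(youden_cutoff(roc_auc(scores, labels))[0])
        assert np.mean(cutoffs) == pytest.approx(crossing, abs=0.15)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80)
        labels = rng.random(80) > 0.5
        a = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        b = bootstrap_auc_ci(scores, labels, B=300, seed=5)
        assert a == b

    def test_perfect_separation_degenerate_interval(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        assert bootstrap_auc_ci(scores, labels, B=1000, seed=0) == (1.0, 1.0)

    def test_b_below_100_rejected(self):
        with pytest.raises(AnalysisError):
            bootstrap_auc_ci([0, 1], [False, True], B=50)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(100 + n)
            scores = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
            labels = np.r_[np.zeros(n, bool), np.ones(n, bool)]
            lo, hi = bootstrap_auc_ci(scores, labels, B=400, seed=3)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_against_closed_form_auc(self):
        """For two normals the true AUC is Phi(dmu / sqrt(s0^2 + s1^2));
        95% percentile intervals must cover it in >= 90% of simulations."""
        true_auc = sps.norm.cdf(1.0 / np.sqrt(2.0))
        covered = 0
        n_sim = 200
        for sim in range(n_sim):
            rng = np.random.default_rng(1000 + sim)
            neg = rng.normal(0.0, 1.0, 100)
            pos = rng.normal(1.0, 1.0, 100)
            scores = np.r_[neg, pos]
            labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
            lo, hi = bootstrap_auc_ci(scores, labels, B=400, seed=sim)
            covered += lo <= true_auc <= hi
        assert covered / n_sim >= 0.90


class TestConfusionMetrics:
    def test_joint_level_worked_example(self):
        """Counts implied by the published joint-level sens/spec at the
        1.07 cut-off reproduce all four printed percentages to 1 d.p."""
        s = confusion_metrics(tp=329, fp=672, fn=89, tn=727)
        assert round(100 * s.sensitivity.value, 1) == 78.7
        assert round(100 * s.specificity.value, 1) == 52.0
        assert round(100 * s.ppv.value, 1) == 32.9
        assert round(100 * s.npv.value, 1) == 89.1
        assert s.tp + s.fn == 418 and s.tn + s.fp == 1399
        for p in (s.sensitivity, s.specificity, s.ppv, s.npv):
            assert p.ci[0] <= p.value <= p.ci[1]

    def test_perfect_classifier(self):
        s = confusion_metrics(1, 0, 0, 1)
        assert (s.sensitivity.value, s.specificity.value, s.ppv.value,
                s.npv.value) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_ppv_reported_as_none(self):
        s = confusion_metrics(tp=0, fp=0, fn=5, tn=7)
        assert s.sensitivity.value == 0.0
        assert s.ppv.value is None and s.ppv.ci is None

    def test_negative_counts_rejected(self):
        with pytest.raises(AnalysisError):
            confusion_metrics(-1, 0, 1, 1)


class TestPredictiveValuesFromRates:
    def test_joint_level_reconstruction(self):
        ppv, npv = predictive_values_from_rates(0.787, 0.520, 418, 1399)
        assert round(100 * ppv, 1) == 32.9
        assert round(100 * npv, 1) == 89.1

    def test_patient_level_reconstruction(self):
        ppv, npv = predictive_values_from_rates(0.929, 0.668, 14, 51)
        assert round(100 * ppv, 1) == 43.3
        assert round(100 * npv, 1) == 97.1

    def test_perfect_rates(self):
        assert predictive_values_from_rates(1.0, 1.0, 10, 90) == (1.0, 1.0)

    def test_closed_form_identity_on_recovered_rates(self):
        """PPV from counts equals s'pi / (s'pi + (1-c')(1-pi)) exactly when
        s', c' are the count-implied rates (algebraic identity), and stays
        within rounding granularity of the closed form at the input rates."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = rng.uniform(0.05, 0.99)
            c = rng.uniform(0.05, 0.99)
            n_pos = int(rng.integers(20, 2000))
            n_neg = int(rng.integers(20, 2000))
            ppv, npv = predictive_values_from_rates(s, c, n_pos, n_neg)
            tp = int(np.floor(s * n_pos + 0.5))
            tn = int(np.floor(c * n_neg + 0.5))
            pi = n_pos / (n_pos + n_neg)
            s2, c2 = tp / n_pos, tn / n_neg
            closed_exact = s2 * pi / (s2 * pi + (1 - c2) * (1 - pi))
            assert ppv == pytest.approx(closed_exact, abs=1e-12)
            closed_input = s * pi / (s * pi + (1 - c) * (1 - pi))
            granularity = 1.0 / (tp + (n_neg - tn)) if tp + (n_neg - tn) else 1.0
            assert abs(ppv - closed_input) <= 2 * granularity


class TestCompareGroups:
    def test_identical_groups_take_anova_branch(self):
        g = {"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5], "c": [1, 2, 3, 4, 5]}
        res = compare_groups(g)
        assert res.test_used == "anova_scheffe"
        assert res.global_p == pytest.approx(1.0)

    def test_variance_outlier_switches_to_kruskal_dunn(self):
        rng = np.random.default_rng(3)
        g = {
            "a": rng.normal(0, 1, 40),
            "b": rng.normal(0, 1, 40),
            "c": rng.normal(0, 10, 40),
        }
        res = compare_groups(g)
        assert res.levene_p < 0.05
        assert res.test_used == "kruskal_dunn"
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_stratified_summed_scores_are_separable(self):
        """Strata drawn at the published summed-score moments and sizes are
        distinguished at p < 0.001 in nearly every replicate."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {
                "high": rng.normal(44.8, 5.8, 14),
                "moderate": rng.normal(35.4, 7.5, 34),
                "low": rng.normal(30.1, 5.6, 17),
            }
            hits += compare_groups(groups).global_p < 0.001
        assert hits >= 95

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError, match="b"):
            compare_groups({"a": [1, 2, 3], "b": [1, 2]})


class TestPearson:
    def test_perfect_linear(self):
        res = pearson_correlation([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
        assert res.r == pytest.approx(1.0)
        assert res.ci[1] == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = pearson_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_ci_contains_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = 0.6 * x + rng.normal(size=60)
        res = pearson_correlation(x, y)
        assert res.ci[0] <= res.r <= res.ci[1]
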