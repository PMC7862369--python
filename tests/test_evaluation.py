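import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_clinical, make_scores
from imsig import (classify_and_tabulate, compare_scores_between_groups,
                   fisher_exact_two_sided, hazard_ratio_two_group, km_logrank,
                   mannwhitney_two_sided, roc_auc, youden_cutoff)
from imsig.evaluation import auc_concordance


def rocify(scores, responses):
    s = make_scores(scores)
    c = make_clinical(responses)
    return roc_auc(s, c)


class TestRocAuc:
    @pytest.mark.parametrize("scores,responses,expected", [
        ([2, 3, 1], ["PR", "CR", "PD"], 1.0),            # perfect separation
        ([1, 3, 2], ["PR", "CR", "PD"], 0.5),            # (0 + 1) / 2
        ([1, 1, 1], ["PR", "CR", "PD"], 0.5),            # all ties
    ])
    def test_known_aucs(self, scores, responses, expected):
        _, auc, _ = rocify(scores, responses)
        assert auc == pytest.approx(expected)

    def test_sd_excluded(self):
        _, auc_with_sd, _ = rocify([2, 3, 1, -99], ["PR", "CR", "PD", "SD"])
        _, auc_without, _ = rocify([2, 3, 1], ["PR", "CR", "PD"])
        assert auc_with_sd == auc_without

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            rocify([1, 2], ["PR", "CR"])

    def test_matches_bruteforce_concordance(self):
        """AUC equals explicit pairwise concordance on random instances."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            x = np.round(rng.normal(size=n), 1)  # rounding makes ties likely
            pairs = [(xi, xj) for xi, yi in zip(x, y) if yi == 1
                     for xj, yj in zip(x, y) if yj == 0]
            brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                             for a, b in pairs])
            assert auc_concordance(x, y) == pytest.approx(brute, abs=1e-12)

    def test_monotone_transform_invariance(self):
        scores = [0.1, 2.2, 1.5, -0.3, 0.9]
        resp = ["PR", "CR", "PD", "PD", "PR"]
        _, auc0, _ = rocify(scores, resp)
        pts0 = rocify(scores, resp)[0]
        _, auc1, _ = rocify(list(np.exp(scores)), resp)
        pts1 = rocify(list(np.exp(scores)), resp)[0]
        assert auc0 == pytest.approx(auc1)
        assert youden_cutoff(pts0)[1] == pytest.approx(youden_cutoff(pts1)[1])

    def test_delong_ci_brackets_auc(self):
        pts, auc, (lo, hi) = rocify([3, 2.5, 2, 1, 0.5, 0.4],
                                    ["CR", "PR", "PD", "PR", "PD", "PD"])
        assert lo <= auc <= hi and 0 <= lo and hi <= 1

    def test_bootstrap_ci_reproducible(self):
        s = make_scores([3, 2.5, 2, 1, 0.5, 0.4])
        c = make_clinical(["CR", "PR", "PD", "PR", "PD", "PD"])
        _, _, ci1 = roc_auc(s, c, ci_method="bootstrap", seed=11, n_boot=200)
        _, _, ci2 = roc_auc(s, c, ci_method="bootstrap", seed=11, n_boot=200)
        assert ci1 == ci2


class TestYoudenCutoff:
    def test_separated_groups_midpoint(self):
        pts, _, _ = rocify([0.9, 0.8, 0.4, 0.3], ["PR", "CR", "PD", "PD"])
        cutoff, j = youden_cutoff(pts)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.6)

    def test_all_scores_equal_gives_zero_j(self):
        pts, _, _ = rocify([1, 1, 1], ["PR", "PD", "PD"])
        _, j = youden_cutoff(pts)
        assert j == pytest.approx(0.0)

    def test_interleaved_exhaustive_scan(self):
        pts, _, _ = rocify([3, 2, 1], ["PR", "PD", "CR"])
        cutoff, j = youden_cutoff(pts)
        assert j == pytest.approx(0.5)
        assert cutoff == pytest.approx(2.5)

    def test_equals_exhaustive_midpoint_scan(self):
        """Maximum J agrees with a brute-force scan of all midpoints."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(4, 15)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            x = np.round(rng.normal(size=n), 1)
            resp = ["PR" if yi else "PD" for yi in y]
            pts, _, _ = rocify(list(x), resp)
            _, j = youden_cutoff(pts)
            uniq = np.unique(x)
            cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                                    [uniq[-1] + 1]])
            brute = max(np.mean(x[y == 1] > c) - np.mean(x[y == 0] > c)
                        for c in cands)
            assert j == pytest.approx(brute, abs=1e-12)


class TestClassifyAndTabulate:
    def puch_data(self):
        """The published melanoma-cohort confusion counts, reconstructed:
        26 predicted nonresponders (23 PD, 1 PR, 2 SD) and 29 predicted
        responders (12 PD, 13 CR/PR, 4 SD)."""
        responses = (["PD"] * 23 + ["PR"] * 1 + ["SD"] * 2
                     + ["PD"] * 12 + ["CR"] * 1 + ["PR"] * 12 + ["SD"] * 4)
        scores = [1.0] * 26 + [2.0] * 29
        ids = [f"p{i}" for i in range(55)]
        return make_scores(scores, ids), make_clinical(responses, ids)

    def test_published_accuracy_example(self):
        scores, clinical = self.puch_data()
        confusion, acc, fisher_p = classify_and_tabulate(
            scores, 1.5, clinical, responder_def="disease_control")
        assert confusion.to_numpy().sum() == 55
        assert acc["pred_nonresponder"] == pytest.approx(23 / 26)
        assert round(100 * acc["pred_nonresponder"], 1) == 88.5
        assert fisher_p < 0.001

    def test_fisher_enumeration_example(self):
        assert fisher_exact_two_sided([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_fisher_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_two_sided(t) == pytest.approx(
                stats.fisher_exact(t)[1], abs=1e-10)

    def test_cutoff_below_min_scores_all_responders(self):
        scores = make_scores([1.0, 2.0, 3.0])
        clinical = make_clinical(["PD", "PR", "CR"])
        confusion, _, _ = classify_and_tabulate(scores, 0.0, clinical,
                                                responder_def="crpr")
        assert confusion.loc["pred_nonresponder"].sum() == 0

    def test_crpr_definition_drops_sd(self):
        scores = make_scores([1.0, 2.0, 3.0])
        clinical = make_clinical(["SD", "PR", "PD"])
        confusion, _, _ = classify_and_tabulate(scores, 1.5, clinical,
                                                responder_def="crpr")
        assert confusion.to_numpy().sum() == 2


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        assert mannwhitney_two_sided([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_identical_values_give_one(self):
        assert mannwhitney_two_sided([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mannwhitney_two_sided([1, 2], [])

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
            assert mannwhitney_two_sided(a, b) == pytest.approx(ref, abs=1e-10)

    def test_group_comparison_wrapper(self):
        scores = make_scores([1, 2, 3, 4])
        groups = pd.Series(["x", "x", "y", "y"],
                           index=["s1", "s2", "s3", "s4"])
        assert compare_scores_between_groups(scores, groups) == pytest.approx(2 / 6)


class TestSurvival:
    def test_identical_event_times_null(self):
        clinical = make_clinical(["PD"] * 4, os_time=[1, 2, 1, 2],
                                 os_event=[1, 1, 1, 1])
        labels = pd.Series(["a", "a", "b", "b"],
                           index=["s1", "s2", "s3", "s4"])
        _, chi2, p = km_logrank(clinical, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_two_singleton_groups_hand_computed(self):
        # death at t=1 (A) and t=2 (B): O-E = 0.5, Var = 0.25 -> chi2 = 1
        clinical = make_clinical(["PD", "PD"], os_time=[1.0, 2.0],
                                 os_event=[1, 1])
        labels = pd.Series(["A", "B"], index=["s1", "s2"])
        _, chi2, p = km_logrank(clinical, labels)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_all_censored_null(self):
        clinical = make_clinical(["PD"] * 4, os_time=[1, 2, 3, 4],
                                 os_event=[0, 0, 0, 0])
        labels = pd.Series(["a", "b", "a", "b"],
                           index=["s1", "s2", "s3", "s4"])
        _, chi2, p = km_logrank(clinical, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-10) and p == pytest.approx(1.0)

    def test_relabeling_invariance_and_monotone_separation(self):
        rng = np.random.default_rng(4)
        n = 30
        base = rng.exponential(10, 2 * n)
        ids = [f"s{i + 1}" for i in range(2 * n)]
        labels = pd.Series(["a"] * n + ["b"] * n, index=ids)
        chis = []
        for hr_mult in (1.0, 2.0, 4.0):
            times = base.copy()
            times[n:] = times[n:] / hr_mult
            clinical = make_clinical(["PD"] * 2 * n, os_time=list(times),
                                     os_event=[1] * 2 * n)
            _, chi2, _ = km_logrank(clinical, labels)
            swapped = labels.map({"a": "b", "b": "a"})
            _, chi2_swap, _ = km_logrank(clinical, swapped)
            assert chi2 == pytest.approx(chi2_swap, abs=1e-9)
            chis.append(chi2)
        assert chis[0] < chis[1] < chis[2]

    def test_identical_groups_hr_one(self):
        clinical = make_clinical(["PD"] * 4, os_time=[1, 2, 1, 2],
                                 os_event=[1, 1, 1, 1])
        labels = pd.Series(["x", "x", "y", "y"],
                           index=["s1", "s2", "s3", "s4"])
        hr, _, _ = hazard_ratio_two_group(clinical, labels)
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_hr_recovers_simulated_effect(self):
        """Exponential survival with true HR 2.0, 500 per arm."""
        rng = np.random.default_rng(2)
        n = 500
        t0 = rng.exponential(10.0, n)
        t1 = rng.exponential(5.0, n)
        times = np.minimum(np.concatenate([t0, t1]), 30.0)
        events = (np.concatenate([t0, t1]) <= 30.0).astype(int)
        ids = [f"s{i + 1}" for i in range(2 * n)]
        clinical = make_clinical(["PD"] * 2 * n, sample_ids=ids,
                                 os_time=list(times), os_event=list(events))
        labels = pd.Series(["g0"] * n + ["g1"] * n, index=ids)
        hr, (lo, hi), unbounded = hazard_ratio_two_group(clinical, labels)
        assert 1.7 <= hr <= 2.3
        assert lo < hr < hi and not unbounded

    def test_single_event_no_crash(self):
        clinical = make_clinical(["PD"] * 4, os_time=[1, 2, 3, 4],
                                 os_event=[1, 0, 0, 0])
        labels = pd.Series(["x", "x", "y", "y"],
                           index=["s1", "s2", "s3", "s4"])
        hr, (lo, hi), unbounded = hazard_ratio_two_group(clinical, labels)
        assert np.isfinite(hr)

    def test_no_events_errors(self):
        clinical = make_clinical(["PD"] * 4, os_time=[1, 2, 3, 4],
                                 os_event=[0, 0, 0, 0])
        labels = pd.Series(["x", "x", "y", "y"],
                           index=["s1", "s2", "s3", "s4"])
        with pytest.raises(ValueError, match="event"):
            hazard_ratio_two_group(clinical, labels)
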