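import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from sdmbaseline.validation import (OmissionTest, THRESHOLD_NAMES,
                                    ValidationReport, aggregate_expert_ranks,
                                    binomial_omission_tests, compute_auc,
                                    eleven_thresholds, evaluate_acceptance,
                                    select_best_model_per_species)


class TestAuc:
    def test_perfect_discrimination(self):
        assert compute_auc([5, 6, 7], [1, 2, 3, 4]) == 1.0

    def test_full_ties_give_half(self):
        assert compute_auc([1.0] * 5, [1.0] * 9) == 0.5

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.normal(0.5, 1, size=30)
            b = rng.normal(0, 1, size=100)
            y = np.r_[np.ones(30), np.zeros(100)]
            expected = roc_auc_score(y, np.r_[p, b])
            assert compute_auc(p, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=2, max_size=20),
           st.lists(st.integers(-100, 100), min_size=2, max_size=20))
    def test_monotone_transform_invariance_and_complement(self, p, b):
        p, b = np.array(p, dtype=float), np.array(b, dtype=float)
        a = compute_auc(p, b)
        # strictly monotone transform (exact on these integers) keeps ranks
        assert compute_auc(p ** 3, b ** 3) == pytest.approx(a, abs=1e-12)
        # swapping classes complements
        assert compute_auc(b, p) == pytest.approx(1 - a, abs=1e-12)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [1.0])


def _fake_surface(n_bg=400, seed=0, concentration=3.0):
    """Background logistic+raw scores from a synthetic fitted surface."""
    rng = np.random.default_rng(seed)
    eta = rng.normal(size=n_bg) * concentration
    raw = np.exp(eta)
    raw /= raw.sum()
    H = -(raw * np.log(raw)).sum()
    c = np.exp(H)
    logistic = c * raw / (1 + c * raw)
    return logistic, raw, H


class TestOmission:
    def test_closed_form_binomial_tail(self):
        """All 10 test presences above a threshold with predicted area
        one-half: p = 0.5^10."""
        logistic, raw, H = _fake_surface()
        t = float(np.median(logistic))
        area = (logistic >= t).mean()
        scores = np.full(10, t + 1e-9)
        from scipy.stats import binom
        p = float(binom.sf(9, 10, area))
        assert p == pytest.approx(area ** 10, rel=1e-9)
        assert p == pytest.approx(0.5 ** 10, rel=0.1)

    def test_whole_area_predicted_present_gives_p_one(self):
        from scipy.stats import binom
        assert binom.sf(7 - 1, 10, 1.0) == 1.0

    def test_no_successes_gives_p_one(self):
        from scipy.stats import binom
        assert binom.sf(0 - 1, 10, 0.3) == 1.0

    def test_eleven_thresholds_and_two_partitions(self):
        logistic, raw, H = _fake_surface()
        rng = np.random.default_rng(1)
        train = rng.choice(logistic, 20)
        test = rng.choice(logistic, 10)
        ths = eleven_thresholds(logistic, raw, H, train, test)
        assert set(ths) == set(THRESHOLD_NAMES)
        assert len(THRESHOLD_NAMES) == 11
        tests = binomial_omission_tests(logistic, raw, H, train, test)
        assert len(tests) == 22
        for t in tests:
            assert 0 <= t.omission <= 1
            assert 0 <= t.predicted_area <= 1
            assert 0 < t.p_value <= 1

    def test_good_model_rejects_null_random_scatter_does_not(self):
        logistic, raw, H = _fake_surface(seed=2)
        top = np.quantile(logistic, 0.97)
        train = np.full(20, top)  # presences concentrated in best habitat
        test = np.full(10, top)
        good = binomial_omission_tests(logistic, raw, H, train, test)
        assert max(t.p_value for t in good) < 0.05
        rng = np.random.default_rng(3)
        train_r = rng.choice(logistic, 20)  # random scatter
        test_r = rng.choice(logistic, 10)
        rand = binomial_omission_tests(logistic, raw, H, train_r, test_r)
        assert max(t.p_value for t in rand) > 0.05

    def test_pvalues_superuniform_under_random_surface(self):
        """Omission p-values under a null (random) placement should not
        reject at 0.05 much more often than 5%."""
        rejections, total = 0, 0
        for trial in range(60):
            logistic, raw, H = _fake_surface(seed=100 + trial, concentration=1.0)
            rng = np.random.default_rng(trial)
            train = rng.choice(logistic, 15)
            test = rng.choice(logistic, 8)
            # fixed-cumulative thresholds are independent of the presences,
            # so their tests are properly calibrated under the null
            tests = [t for t in binomial_omission_tests(logistic, raw, H, train, test)
                     if t.name.startswith("fixed_cumulative")]
            rejections += sum(t.p_value < 0.05 for t in tests)
            total += len(tests)
        assert rejections / total <= 0.05 + 0.04  # Monte-Carlo slack


def _report(train=0.96, test=0.93, p=0.001, n=22):
    tests = [OmissionTest("fixed_cumulative_1", 0.2, 0.1, 0.3, p,
                          "train" if i % 2 else "test") for i in range(n)]
    return ValidationReport(mean_train_auc=train, mean_test_auc=test,
                            omission_tests=tests, n_replicates=1)


class TestAcceptanceRule:
    def test_all_pass(self):
        d = evaluate_acceptance(_report())
        assert d.accepted and d.auc_ok and d.omission_ok and d.gap_ok

    def test_auc_below_point_nine_rejected(self):
        d = evaluate_acceptance(_report(train=0.92, test=0.89))
        assert not d.accepted and not d.auc_ok and d.omission_ok and d.gap_ok

    def test_single_omission_p_at_six_percent_rejected(self):
        rep = _report()
        rep.omission_tests[7] = OmissionTest("equate_entropy", 0.2, 0.1, 0.3,
                                             0.06, "test")
        d = evaluate_acceptance(rep)
        assert not d.accepted and not d.omission_ok and d.auc_ok and d.gap_ok
        assert d.max_omission_p == 0.06

    def test_gap_of_three_percent_passes_five_fails(self):
        # 0.96 train / 0.93 test: |0.96-0.93|/0.96 = 3.1% < 5%
        d = evaluate_acceptance(_report(train=0.96, test=0.93))
        assert d.gap_ok and d.auc_gap == pytest.approx(0.03125)
        # 0.99 train / 0.93 test: 6.1% > 5%
        d2 = evaluate_acceptance(_report(train=0.99, test=0.93))
        assert not d2.gap_ok and not d2.accepted

    def test_absolute_gap_mode(self):
        d = evaluate_acceptance(_report(train=0.99, test=0.95),
                                gap_mode="absolute")
        assert d.gap_ok and d.auc_gap == pytest.approx(0.04)

    def test_monotone_improvement_never_flips_to_rejected(self):
        base = _report(train=0.96, test=0.93, p=0.04)
        assert evaluate_acceptance(base).accepted
        better = _report(train=0.96, test=0.95, p=0.001)
        assert evaluate_acceptance(better).accepted


class TestExpertRanks:
    def test_mean_of_two_experts(self):
        t = pd.DataFrame({"m1": [4, 5]}, index=["e1", "e2"])
        sel = aggregate_expert_ranks(t, top_k=1)
        assert sel.mean_ranks["m1"] == 4.5

    def test_boundary_tie_keeps_both(self):
        t = pd.DataFrame({"a": [3, 3], "b": [4.5, 4.5], "c": [4.5, 4.5],
                          "d": [2, 2]}, index=["e1", "e2"])
        sel = aggregate_expert_ranks(t, top_k=2)
        assert sel.selected == ["b", "c"]
        assert not sel.tie_broken

    def test_all_tied_takes_first_by_id_and_flags(self):
        t = pd.DataFrame({c: [3, 3] for c in "dcba"}, index=["e1", "e2"])
        sel = aggregate_expert_ranks(t, top_k=2)
        assert sel.selected == ["a", "b"]
        assert sel.tie_broken

    def test_out_of_scale_rank_rejected(self):
        t = pd.DataFrame({"a": [6]})
        with pytest.raises(ValueError):
            aggregate_expert_ranks(t)


class TestBestModelSelection:
    def test_argmax_by_test_auc(self):
        cands = {"3": _report(test=0.9887), "9": _report(test=0.97)}
        assert select_best_model_per_species(cands) == ("3", False)

    def test_single_candidate(self):
        assert select_best_model_per_species({"9": _report()}) == ("9", False)

    def test_exact_tie_goes_to_lower_id_flagged(self):
        cands = {"9": _report(test=0.95), "3": _report(test=0.95)}
        assert select_best_model_per_species(cands) == ("3", True)
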