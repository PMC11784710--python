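"""ADASYN augmentation, fold plans, CV harness, metrics, rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from cbrisk.cohort import Group
from cbrisk.scoring import train
from cbrisk.simulate import GeneratorParams, generate_cohort
from cbrisk.validation import (
    TABLE_FOLD_TEST_PAIRS,
    ConfusionMatrix,
    adasyn_augment,
    confusion_metrics,
    evaluate_round,
    make_fold_plan,
    rank_sum_test,
    run_cross_validation,
    subject_feature_vector,
)


class TestAdasyn:
    def test_study_gap_yields_17(self):
        rng = np.random.default_rng(0)
        minority = rng.normal(size=(8, 6))
        out = adasyn_augment(minority, majority_count=25, seed=1)
        assert out.shape == (17, 6)

    def test_balanced_classes_yield_none(self):
        minority = np.random.default_rng(0).normal(size=(5, 3))
        assert adasyn_augment(minority, majority_count=5, seed=0).shape == (0, 3)
        assert adasyn_augment(minority, majority_count=3, seed=0).shape == (0, 3)

    def test_minority_below_two_errors(self):
        with pytest.raises(ValueError, match="2 minority"):
            adasyn_augment(np.ones((1, 3)), majority_count=5, seed=0)

    def test_synthetic_points_are_convex_combinations(self):
        rng = np.random.default_rng(3)
        minority = rng.normal(size=(6, 4))
        out = adasyn_augment(minority, majority_count=20, seed=7)
        for v in out:
            # v = x_i + lam (x_z - x_i) for some minority pair (i, z): check
            # collinearity and 0 <= lam <= 1 against every pair
            found = False
            for i, z in itertools.permutations(range(6), 2):
                d = minority[z] - minority[i]
                rel = v - minority[i]
                lam = rel @ d / (d @ d)
                if 0 <= lam <= 1 and np.allclose(rel, lam * d, atol=1e-9):
                    found = True
                    break
            assert found, "synthetic vector off all minority segments"

    def test_deterministic_given_seed(self):
        minority = np.random.default_rng(5).normal(size=(8, 10))
        a = adasyn_augment(minority, 25, seed=9)
        b = adasyn_augment(minority, 25, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_majority_neighbours_skew_allocation(self):
        # minority points sitting inside the majority cloud should generate
        # more synthetics than isolated ones; counts still close the gap
        minority = np.vstack(
            [np.zeros((4, 2)), np.full((4, 2), 100.0) + np.eye(2)[0] * np.arange(4)[:, None]]
        )
        majority = np.random.default_rng(0).normal(0.0, 1.0, size=(25, 2))
        out = adasyn_augment(minority, 25, seed=2, majority=majority)
        assert out.shape == (17, 2)
        near_origin = (np.linalg.norm(out, axis=1) < 50).sum()
        assert near_origin > 17 / 2


class TestFoldPlan:
    def test_table_preset_round_one(self):
        ids = [sid for pair in TABLE_FOLD_TEST_PAIRS for sid in pair]
        plan = make_fold_plan(ids, preset="table")
        assert set(plan.rounds[0]["test_ids"]) == {"20180101008", "20180101001"}
        tested = [s for r in plan.rounds for s in r["test_ids"]]
        assert sorted(tested) == sorted(ids)

    def test_seeded_plan_reproducible(self):
        ids = [f"s{i}" for i in range(8)]
        assert make_fold_plan(ids, seed=3) == make_fold_plan(ids, seed=3)

    def test_six_ids_three_rounds(self):
        plan = make_fold_plan([f"s{i}" for i in range(6)], seed=0)
        assert len(plan.rounds) == 3
        for r in plan.rounds:
            assert len(r["test_ids"]) == 2 and len(r["train_ids"]) == 4

    def test_odd_count_errors(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b", "c"], seed=0)

    def test_table_preset_rejects_foreign_ids(self):
        with pytest.raises(ValueError, match="original"):
            make_fold_plan([f"s{i}" for i in range(8)], preset="table")


class TestConfusionMetrics:
    def test_uniform_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=1, fp=1, fn=1, tn=1))
        assert all(v == pytest.approx(0.5) for v in m.values())

    def test_perfect_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_hand_computed(self):
        m = confusion_metrics(ConfusionMatrix(tp=3, fp=1, fn=1, tn=3))
        assert m == pytest.approx(
            {"accuracy": 0.75, "precision": 0.75, "recall": 0.75, "f1": 0.75}
        )

    def test_zero_denominator_warns(self):
        with pytest.warns(UserWarning, match="denominator"):
            m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=2, tn=2))
        assert m["precision"] == 0.0 and m["f1"] == 0.0

    def test_order_invariance_via_aggregation(self):
        # accuracy is the sample-weighted mean of class-conditional rates
        cm = ConfusionMatrix(tp=6, fp=2, fn=3, tn=8)
        m = confusion_metrics(cm)
        pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
        expected = (m["recall"] * pos + (cm.tn / neg) * neg) / (pos + neg)
        assert m["accuracy"] == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix())


class TestCrossValidation:
    def test_round_never_sees_test_subjects(self, study_cohort):
        # leakage check: the round's model must equal a model retrained on
        # the training ids alone, bit-exactly
        pre_ids = [s.subject_id for s in study_cohort.group_subjects(Group.PREDIABETES)]
        plan = make_fold_plan(pre_ids, seed=1)
        entry = plan.rounds[0]
        result = evaluate_round(study_cohort, entry, control_seed=5)
        retrained = train(study_cohort.subset(entry["train_ids"]))
        direct = evaluate_round(study_cohort, entry, control_seed=5)
        assert result.confusion == direct.confusion
        np.testing.assert_array_equal(
            train(study_cohort.subset(entry["train_ids"])).psi.values,
            retrained.psi.values,
        )

    def test_full_run_shapes_and_averages(self, study_cohort):
        report = run_cross_validation(study_cohort, seed=7)
        assert len(report.rounds) == 4
        for r in report.rounds:
            assert r.confusion.total == 38  # 19 prediabetes-labelled + 19 controls
        for name in ("accuracy", "precision", "recall", "f1"):
            mean = np.mean([r.metrics[name] for r in report.rounds])
            assert report.averages[name] == pytest.approx(mean)
            assert 0.0 <= report.averages[name] <= 1.0

    def test_strong_separation_scores_high(self, study_cohort):
        report = run_cross_validation(study_cohort, seed=3)
        assert report.averages["accuracy"] >= 0.7

    def test_no_leak_mode_runs(self, study_cohort):
        report = run_cross_validation(study_cohort, seed=7, no_leak=True)
        assert len(report.rounds) == 4
        assert report.config["no_leak"] is True

    def test_null_cohort_near_chance(self):
        # identical group distributions: accuracy should hover around 0.5
        params = GeneratorParams(
            seed=11,
            rr_baseline_prediabetes=(17.1, 1.5),
            oxy_dip_mean_prediabetes=1.5,
            oxy_dip_sd_prediabetes=0.4,
            glucose_baseline_prediabetes=(90.0, 5.0),
            postprandial_rise_prediabetes=20.0,
            glucose_decay_prediabetes=8.0,
        )
        accs = [
            run_cross_validation(
                generate_cohort(dataclasses_replace(params, seed=s)), seed=s
            ).averages["accuracy"]
            for s in (11, 12)
        ]
        assert 0.25 <= np.mean(accs) <= 0.75

    def test_feature_vector_layout(self, study_cohort):
        s = study_cohort.subjects[0]
        v = subject_feature_vector(s)
        np.testing.assert_allclose(v[:80], s.hr)
        np.testing.assert_allclose(v[80:], s.rr)


def dataclasses_replace(params, **kw):
    import dataclasses

    return dataclasses.replace(params, **kw)


def _exact_mwu_oracle(x, y):
    """Brute-force null enumeration of the Mann-Whitney U distribution."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(
            sum(1 for xi in xs for yj in ys if xi > yj)
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        )
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestRankSum:
    def test_tiny_sample_exact(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res["U"] == 0.0
        assert res["p_two_sided"] == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 4)
        y = rng.normal(0.8, 1, 6)
        res = rank_sum_test(x, y)
        u_oracle, p_oracle = _exact_mwu_oracle(x, y)
        assert res["U"] == pytest.approx(u_oracle)
        assert res["p_two_sided"] == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_samples_not_significant(self):
        x = [3.0, 1.0, 2.0, 5.0]
        res = rank_sum_test(x, list(x))
        assert res["p_two_sided"] >= 0.99

    def test_asymptotic_matches_closed_form(self):
        # tied data forces the normal approximation; verify against the
        # tie-corrected closed form with continuity correction
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(0, 2, 30), 0)
        y = np.round(rng.normal(1, 2, 35), 0)
        res = rank_sum_test(x, y)
        n, m = len(x), len(y)
        N = n + m
        u1 = res["U"]
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
        sd = math.sqrt(n * m / 12 * ((N + 1) - tie_term))
        z = (abs(u1 - n * m / 2) - 0.5) / sd
        assert res["p_two_sided"] == pytest.approx(2 * norm.sf(z), abs=1e-6)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
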