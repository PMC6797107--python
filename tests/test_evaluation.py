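"""Protocols: splits, confusion matrices, filters, diagnostics."""

import numpy as np
import pytest

import dyadrel as dr
from dyadrel.bayes import PosteriorTrace
from dyadrel.evaluation import ExperimentConfig, to_meta
from dyadrel.io import ValidationError

from conftest import parallel_dyad


def trace_from_winners(winners, relations=("a", "b"), dyad_id="d"):
    """A degenerate trace whose per-event argmax follows ``winners``."""
    n = len(winners)
    post = np.full((n, len(relations)), 0.1 / (len(relations) - 1))
    for k, w in enumerate(winners):
        post[k] = (1 - 0.9) / (len(relations) - 1)
        post[k, relations.index(w)] = 0.9
    return PosteriorTrace(dyad_id=dyad_id, relations=tuple(relations),
                          times=np.arange(n, dtype=float), posteriors=post,
                          valid=np.ones(n, bool), alpha=1.0,
                          p0=np.full(len(relations), 1 / len(relations)))


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        dyads = [parallel_dyad() for _ in range(10)]
        train, test = dr.split_dyads(dyads, 0.3, np.random.default_rng(0))
        assert len(train) == 3 and len(test) == 7
        ids = {id(d) for d in train} | {id(d) for d in test}
        assert len(ids) == 10

    def test_same_seed_same_split(self):
        dyads = [parallel_dyad() for _ in range(20)]
        t1, _ = dr.split_dyads(dyads, 0.3, np.random.default_rng(5))
        t2, _ = dr.split_dyads(dyads, 0.3, np.random.default_rng(5))
        assert [id(d) for d in t1] == [id(d) for d in t2]

    def test_never_in_train_frequency_matches_protocol(self):
        """P(a dyad never trains over 50 reps of a 30% split) ~ 0.7^50."""
        rng = np.random.default_rng(1)
        dyads = [parallel_dyad() for _ in range(40)]
        never = np.ones(len(dyads), bool)
        reps = 50
        for _ in range(reps):
            train, _ = dr.split_dyads(dyads, 0.3, rng)
            chosen = {id(d) for d in train}
            for i, d in enumerate(dyads):
                if id(d) in chosen:
                    never[i] = False
        # 0.7^50 ~ 2e-8: essentially no dyad should remain unseen
        assert never.sum() == 0


class TestConfusionMatrices:
    def test_perfect_classifier_identity(self):
        traces = [trace_from_winners(["a"] * 4), trace_from_winners(["b"] * 4)]
        cm = dr.confusion_by_event(traces, ["a", "b"], np.random.default_rng(0))
        np.testing.assert_allclose(cm.values, [[100, 0], [0, 100]])

    def test_by_event_matches_hand_count(self):
        traces = [trace_from_winners(["a", "a", "b"]),
                  trace_from_winners(["b", "b", "b"])]
        cm = dr.confusion_by_event(traces, ["a", "b"], np.random.default_rng(0))
        np.testing.assert_allclose(cm.values, [[200 / 3, 100 / 3], [0, 100]])

    def test_voting_matches_hand_count(self):
        traces = [trace_from_winners(["a", "a", "b"]),
                  trace_from_winners(["b", "a", "b"])]
        cm = dr.confusion_by_trajectory_voting(
            traces, ["a", "a"], np.random.default_rng(0), row_labels=("a",))
        np.testing.assert_allclose(cm.values, [[50, 50]])

    def test_voting_equals_by_event_for_single_event_traces(self):
        traces = [trace_from_winners(["a"]), trace_from_winners(["b"]),
                  trace_from_winners(["b"])]
        gt = ["a", "a", "b"]
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        cm_e = dr.confusion_by_event(traces, gt, rng1)
        cm_v = dr.confusion_by_trajectory_voting(traces, gt, rng2)
        np.testing.assert_allclose(cm_e.values, cm_v.values)

    def test_metric_confusion_hand_count(self):
        cm = dr.confusion_metric(
            assignments=["a", "b", "b", "a", "b"],
            ground_truth=["a", "a", "b", "b", "b"],
            col_labels=("a", "b"))
        np.testing.assert_allclose(cm.values, [[50, 50], [100 / 3, 200 / 3]])

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        winners = [["a", "b"][rng.integers(2)] for _ in range(30)]
        traces = [trace_from_winners([w] * 3) for w in winners]
        gt = [["a", "b"][rng.integers(2)] for _ in range(30)]
        cm = dr.confusion_by_event(traces, gt, rng)
        np.testing.assert_allclose(cm.values.sum(axis=1), 100.0, atol=0.01)

    def test_unnormalizable_rows_rejected(self):
        with pytest.raises(ValidationError):
            dr.confusion_metric(["a"], ["a"], col_labels=("a", "b"),
                                row_labels=("a", "b"))


class TestFilters:
    def test_median_filter_strictly_greater(self):
        items = ["a", "b", "c", "d", "e"]
        kept = dr.filter_by_median_length(items, [1, 2, 3, 4, 5])
        assert kept == ["d", "e"]

    def test_all_equal_lengths_empty(self):
        assert dr.filter_by_median_length([1, 2, 3], [7, 7, 7]) == []

    def test_children_filter_targets_families_only(self):
        fam_child = parallel_dyad(relation="families")
        fam_child.age_a, fam_child.age_b = 34, 8
        fam_adult = parallel_dyad(relation="families")
        fam_adult.age_a, fam_adult.age_b = 40, 38
        couple = parallel_dyad(relation="couples")
        couple.age_a, couple.age_b = 40, 38
        kept = dr.families_with_children_filter([fam_child, fam_adult, couple])
        assert fam_child in kept and couple in kept and fam_adult not in kept

    def test_missing_family_ages_is_error(self):
        fam = parallel_dyad(relation="families")
        with pytest.raises(ValidationError):
            dr.families_with_children_filter([fam])


class TestRunExperiment:
    def test_flat_mode_shape_and_reproducibility(self, small_dataset):
        dyads, observations = small_dataset
        cfg = ExperimentConfig(mode="flat", classifier="bayes", repetitions=2,
                               seed=3)
        r1 = dr.run_experiment(cfg, dyads, observations)
        r2 = dr.run_experiment(cfg, dyads, observations)
        cm = r1.matrices["by_event"]
        assert cm.values.shape == (4, 4)
        np.testing.assert_array_equal(cm.values,
                                      r2.matrices["by_event"].values)

    def test_stage1_shapes(self, small_dataset):
        dyads, observations = small_dataset
        cfg = ExperimentConfig(mode="hierarchical_stage1", classifier="bayes",
                               repetitions=1, seed=0)
        res = dr.run_experiment(cfg, dyads, observations)
        assert res.matrices["by_event"].values.shape == (2, 2)
        assert res.matrices["by_event_detailed"].values.shape == (4, 2)

    def test_stage2_three_by_three(self, small_dataset):
        dyads, observations = small_dataset
        cfg = ExperimentConfig(mode="hierarchical_stage2", classifier="emd",
                               repetitions=1, seed=0)
        res = dr.run_experiment(cfg, dyads, observations)
        cm = res.matrices["metric"]
        assert cm.values.shape == (3, 3)
        assert cm.row_labels == ("families", "couples", "friends")
        np.testing.assert_allclose(cm.values.sum(axis=1), 100.0, atol=0.01)

    def test_single_repetition_equals_direct_run(self, small_dataset):
        dyads, observations = small_dataset
        cfg = ExperimentConfig(mode="flat", classifier="emd", repetitions=1,
                               seed=9)
        res = dr.run_experiment(cfg, dyads, observations)
        assert res.matrices["metric"].values is not None
        np.testing.assert_allclose(res.matrices["metric"].values,
                                   res.per_rep["metric"][0].values, atol=1e-9)

    def test_meta_mapping(self):
        assert to_meta("colleagues") == "work"
        assert {to_meta(r) for r in ("families", "couples", "friends")} == {"leisure"}


class TestEntropyDistance:
    def test_deterministic_relation_zero(self):
        x = np.random.default_rng(0).random(20_000)
        assert dr.normalized_entropy_distance(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_independent_near_one(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(100_000), rng.random(100_000)
        assert dr.normalized_entropy_distance(x, y) > 0.95

    def test_correlated_strictly_between(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50_000)
        y = 0.7 * x + 0.7 * rng.standard_normal(50_000)
        d = dr.normalized_entropy_distance(x, y)
        assert 0.05 < d < 0.95

    def test_constant_input_convention(self):
        assert dr.normalized_entropy_distance(np.ones(100),
                                              np.arange(100.0)) == 1.0

    def test_observables_nearly_conditionally_independent(self, small_dataset):
        """Within a relation class, pairwise observable dependence is weak."""
        dyads, observations = small_dataset
        vals = {o: [] for o in ("delta", "vg", "omega")}
        for d in dyads:
            if d.relation != "colleagues":
                continue
            for s in observations[d.dyad_id]:
                for o in vals:
                    vals[o].append(getattr(s, o))
        d1 = dr.normalized_entropy_distance(np.array(vals["delta"]),
                                            np.array(vals["vg"]))
        assert d1 > 0.7
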