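import json

import numpy as np
import pytest

from skinid import (
    EvalConfig,
    ReferenceSet,
    classify_closed,
    cross_period_eval,
    cutoff_sweep,
    leave_one_out,
    metrics_compare,
    open_set_threshold_sweep,
    rarefaction_sweep,
    reference_count_trials,
    time_effect_trials,
    to_relative_abundance,
)
from skinid.simulate import SyntheticConfig, generate_cohort

from conftest import make_table


@pytest.fixture(scope="module")
def separated_table():
    """Each individual's samples identical to each other, disjoint across."""
    counts = {}
    owners = {}
    for i, ind in enumerate(["A", "B", "C"]):
        vec = [0] * 6
        vec[2 * i] = 80
        vec[2 * i + 1] = 20
        for t in range(2):
            counts[f"{ind}{t+1}"] = vec
            owners[f"{ind}{t+1}"] = ind
    return make_table(counts, owners)


class TestLeaveOneOut:
    def test_separated_cohort_is_perfect(self, separated_table):
        report = leave_one_out(separated_table)
        assert report.accuracy == 1.0
        assert report.confusion.n_tp == separated_table.n_samples

    def test_all_identical_samples_all_tie(self):
        counts = {f"s{i}": [50, 50] for i in range(4)}
        owners = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        report = leave_one_out(make_table(counts, owners))
        assert all(row["tie"] for row in report.rows)

    def test_matches_per_query_classifier(self, toy_table):
        """The matrix fast path must agree with classify_closed per query."""
        report = leave_one_out(toy_table)
        by_query = {row["query_sample_id"]: row for row in report.rows}
        for sid in toy_table.sample_ids:
            refset = ReferenceSet.from_table(toy_table, exclude=[sid])
            res = classify_closed(toy_table.profile(sid), refset)
            assert by_query[sid]["predicted"] == res.predicted
            assert by_query[sid]["min_distance"] == pytest.approx(
                res.min_distance, abs=1e-9)

    def test_accuracy_recomputable_from_rows(self, toy_table):
        report = leave_one_out(toy_table)
        correct = sum(r["predicted"] == r["true_owner"] for r in report.rows)
        assert report.accuracy == correct / len(report.rows)

    def test_singleton_individual_is_named(self):
        table = make_table({"a1": [1, 0], "a2": [1, 0], "b1": [0, 1]},
                           {"a1": "A", "a2": "A", "b1": "B"})
        with pytest.raises(ValueError, match="B"):
            leave_one_out(table)


class TestCrossPeriod:
    def test_identical_periods_are_perfect(self, separated_table):
        periods = {s: ("year1" if s.endswith("1") else "year2")
                   for s in separated_table.sample_ids}
        table = make_table(
            {s: separated_table.data[s].tolist() for s in separated_table.sample_ids},
            {s: separated_table.metadata.loc[s, "individual_id"]
             for s in separated_table.sample_ids},
            periods=periods)
        report = cross_period_eval(table, "year1", "year2")
        assert report.accuracy == 1.0
        assert len(report.rows) == 3  # one query per individual in year2

    def test_missing_period_rejected(self, separated_table):
        with pytest.raises(ValueError, match="year9"):
            cross_period_eval(separated_table, "year9", "year1")

    def test_individual_absent_from_period_rejected(self):
        table = make_table(
            {"a1": [1, 0], "a2": [1, 0], "b1": [0, 1], "b2": [0, 1]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            periods={"a1": "year1", "a2": "year2", "b1": "year1", "b2": "year1"})
        with pytest.raises(ValueError, match="B"):
            cross_period_eval(table, "year1", "year2")


@pytest.fixture(scope="module")
def driftfree_rel():
    cfg = SyntheticConfig(n_individuals=6, n_timepoints_per_period=3,
                          n_periods=2, period_drift=0.0, n_otus=120,
                          read_depth=5000, seed=11)
    table, _ = generate_cohort(cfg)
    return to_relative_abundance(table)


class TestTimeEffectTrials:
    def test_driftfree_same_and_cross_agree(self, driftfree_rel):
        config = EvalConfig(n_trials=60, seed=2)
        same = time_effect_trials(driftfree_rel, "same_period", config)
        cross = time_effect_trials(driftfree_rel, "cross_period", config)
        a = same.conditions[0]["mean_accuracy"]
        b = cross.conditions[0]["mean_accuracy"]
        assert abs(a - b) < 0.1  # Monte-Carlo tolerance under the no-drift null

    def test_drift_favors_same_period(self, default_rel):
        config = EvalConfig(n_trials=100, seed=2)
        same = time_effect_trials(default_rel, "same_period", config)
        cross = time_effect_trials(default_rel, "cross_period", config)
        assert same.conditions[0]["mean_accuracy"] >= \
            cross.conditions[0]["mean_accuracy"]

    def test_deterministic_rerun(self, driftfree_rel):
        config = EvalConfig(n_trials=20, seed=9)
        r1 = time_effect_trials(driftfree_rel, "same_period", config)
        r2 = time_effect_trials(driftfree_rel, "same_period", config)
        assert r1.conditions == r2.conditions

    def test_bad_pairing_rejected(self, driftfree_rel):
        with pytest.raises(ValueError):
            time_effect_trials(driftfree_rel, "weekly", EvalConfig())


class TestReferenceCountTrials:
    def test_max_refs_on_separated_cohort_is_perfect(self, separated_table):
        config = EvalConfig(n_trials=10, seed=0)
        report = reference_count_trials(separated_table, config, ref_counts=[1])
        assert report.conditions[0]["accuracies"] == [1.0] * 10

    def test_more_references_help_on_noisy_cohort(self, noisy_rel):
        config = EvalConfig(n_trials=100, seed=0)
        report = reference_count_trials(noisy_rel, config, ref_counts=[1, 5])
        acc = {c["value"]: c["mean_accuracy"] for c in report.conditions}
        assert acc[5] >= acc[1]

    def test_deterministic_rerun(self, toy_table):
        config = EvalConfig(n_trials=15, seed=4)
        r1 = reference_count_trials(toy_table, config, ref_counts=[1, 2])
        r2 = reference_count_trials(toy_table, config, ref_counts=[1, 2])
        assert r1.conditions == r2.conditions

    def test_excessive_ref_count_rejected(self, toy_table):
        with pytest.raises(ValueError):
            reference_count_trials(toy_table, EvalConfig(), ref_counts=[3])


class TestCutoffSweep:
    def test_zero_cutoff_equals_plain_loo(self, default_rel):
        config = EvalConfig(seed=0)
        sweep = cutoff_sweep(default_rel, cutoffs=[0.0, 1e-1], config=config)
        plain = leave_one_out(default_rel, config)
        by_cutoff = {c["value"]: c["accuracy"] for c in sweep.conditions}
        assert by_cutoff[0.0] == plain.accuracy

    def test_minor_taxa_carry_the_signal(self, default_rel):
        # individuality planted below 1e-2 abundance: harsh cut-off hurts
        sweep = cutoff_sweep(default_rel, cutoffs=[0.0, 1e-1])
        by_cutoff = {c["value"]: c["accuracy"] for c in sweep.conditions}
        assert by_cutoff[0.0] >= by_cutoff[1e-1]
        assert by_cutoff[1e-1] < 0.8  # collapses toward chance

    def test_counts_table_rejected(self, toy_table):
        with pytest.raises(ValueError):
            cutoff_sweep(toy_table, cutoffs=[0.0])


class TestRarefactionSweep:
    def test_depth_at_minimum_total_drops_nothing(self, toy_table):
        min_total = int(toy_table.data.sum(axis=0).min())
        report = rarefaction_sweep(toy_table, depths=[min_total], n_reps=2,
                                   config=EvalConfig(seed=1))
        assert len(report.conditions) == 1

    def test_deeper_sequencing_helps(self, default_cohort):
        table, _ = default_cohort
        report = rarefaction_sweep(table, depths=[100, 20000], n_reps=5,
                                   config=EvalConfig(seed=0))
        acc = {c["value"]: c["mean_accuracy"] for c in report.conditions}
        assert acc[20000] >= acc[100]

    def test_deterministic_across_whole_sweep(self, toy_table):
        min_total = int(toy_table.data.sum(axis=0).min())
        kw = dict(depths=[min_total // 2], n_reps=3, config=EvalConfig(seed=5))
        r1 = rarefaction_sweep(toy_table, **kw)
        r2 = rarefaction_sweep(toy_table, **kw)
        assert r1.conditions == r2.conditions

    def test_proportions_table_rejected(self, default_rel):
        with pytest.raises(ValueError):
            rarefaction_sweep(default_rel, depths=[100], n_reps=1)


@pytest.fixture(scope="module")
def sweep(default_rel):
    D_max = 80.0  # comfortably above the largest observed mean distance
    grid = [1e-9] + list(np.linspace(1.0, D_max, 30)) + [1e9]
    return open_set_threshold_sweep(default_rel, grid), grid


class TestOpenSetSweep:
    def test_tp_curve_nondecreasing_tn_nonincreasing(self, sweep):
        report, _ = sweep
        tp = [c["tp_ratio"] for c in report.conditions]
        tn = [c["tn_ratio"] for c in report.conditions]
        assert all(a <= b + 1e-12 for a, b in zip(tp, tp[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(tn, tn[1:]))

    def test_endpoints_match_forced_bounds(self, sweep, default_rel):
        report, _ = sweep
        assert report.conditions[0]["tp_ratio"] == 0.0
        assert report.conditions[0]["tn_ratio"] == 1.0
        assert report.conditions[-1]["tn_ratio"] == 0.0
        closed = leave_one_out(default_rel)
        assert report.conditions[-1]["tp_ratio"] == closed.accuracy

    def test_curves_recomputable_from_per_query_rows(self, sweep):
        """Each query flips at one threshold; the curves follow from the
        stored per-query distances by direct counting."""
        report, grid = sweep
        correct = np.array([r["present_correct"] for r in report.rows])
        d_pres = np.array([r["present_min_distance"] for r in report.rows])
        d_abs = np.array([r["absent_min_distance"] for r in report.rows])
        for cond in report.conditions:
            t = cond["value"]
            assert cond["tp_ratio"] == pytest.approx(
                np.mean(correct & (d_pres < t)))
            assert cond["tn_ratio"] == pytest.approx(np.mean(d_abs >= t))

    def test_curves_cross_on_accurate_cohort(self, sweep):
        report, _ = sweep
        diff = [c["tp_ratio"] - c["tn_ratio"] for c in report.conditions]
        assert diff[0] < 0 < diff[-1]  # a crossing exists on the grid


class TestMetricsCompare:
    def test_one_row_per_metric(self, toy_table):
        report = metrics_compare(toy_table)
        assert [c["value"] for c in report.conditions] == \
            ["canberra", "bray_curtis", "jaccard"]

    def test_each_row_equals_its_own_loo(self, toy_table):
        report = metrics_compare(toy_table, metrics=["bray_curtis"])
        loo = leave_one_out(toy_table, EvalConfig(metric="bray_curtis"))
        assert report.conditions[0]["accuracy"] == loo.accuracy


class TestReportSerialization:
    def test_report_files_written_and_json_parses(self, toy_table, tmp_path):
        report = leave_one_out(toy_table)
        paths = report.write(tmp_path, "loo")
        payload = json.loads(paths["json"].read_text())
        assert payload["accuracy"] == report.accuracy
        assert payload["config"]["metric"] == "canberra"
        assert paths["rows"].exists()

    def test_tidy_long_format(self, noisy_rel):
        config = EvalConfig(n_trials=5, seed=1)
        report = reference_count_trials(noisy_rel, config, ref_counts=[1, 2])
        tidy = report.tidy()
        assert set(tidy.columns) == {"parameter", "value", "trial", "accuracy"}
        assert len(tidy) == 10
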