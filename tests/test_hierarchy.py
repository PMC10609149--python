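import numpy as np
import pytest

from metabotree.core_io import DescriptorMatrix, LabeledDataset, SubLabel, TopLabel
from metabotree.errors import ValidationError
from metabotree.hierarchy import (
    EvaluationReport,
    cross_validate,
    cross_validate_naive,
    evaluate_independent,
    fit_two_stage,
    overall_accuracy,
    predict_two_stage,
    stratified_fold_indices,
)
from metabotree.synthetic import SyntheticSpec, generate_hierarchical_dataset

from conftest import fast_config


@pytest.fixture(scope="module")
def small_data():
    """Compact hierarchical dataset for fast fit/predict tests."""
    _, data = generate_hierarchical_dataset(
        SyntheticSpec(
            n_per_leaf={"AD": 12, "SQ": 12, "SC": 12}, n_dims=40, noise_sd=0.1, seed=5
        )
    )
    return data


@pytest.fixture(scope="module")
def small_model(small_data):
    cfg = fast_config(seed=5)
    return fit_two_stage(small_data, cfg, seed=5)


class TestOverallAccuracy:
    def test_paper_worked_example(self):
        assert overall_accuracy(0.962, 0.911, 0.487, 0.513) == pytest.approx(0.920, abs=5e-4)

    def test_perfect_classifiers(self):
        assert overall_accuracy(1.0, 1.0, 0.3, 0.7) == 1.0

    def test_closed_form_equal_fractions(self, rng):
        for _ in range(20):
            a, b = rng.random(2)
            assert overall_accuracy(a, b, 0.5, 0.5) == pytest.approx(0.5 * a * (1 + b), abs=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            overall_accuracy(0.9, 0.9, 0.6, 0.6)

    def test_inputs_in_unit_interval(self):
        with pytest.raises(ValidationError):
            overall_accuracy(1.1, 0.9, 0.5, 0.5)

    def test_monotone_in_each_stage(self):
        # grid check: overall never decreases when a stage accuracy increases
        grid = np.linspace(0, 1, 11)
        for ns in (0.2, 0.487, 0.8):
            for s2 in grid:
                vals = [overall_accuracy(s1, s2, ns, 1 - ns) for s1 in grid]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
            for s1 in grid:
                vals = [overall_accuracy(s1, s2, ns, 1 - ns) for s2 in grid]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestEvaluationReport:
    def test_internal_consistency_enforced(self):
        with pytest.raises(ValidationError):
            EvaluationReport(
                stage1_acc=0.9, stage1_sd=0.0, stage2_acc=0.9, stage2_sd=0.0,
                ns_frac=0.5, sc_frac=0.5, overall_acc=0.123, protocol="cv5",
            )

    def test_consistent_report_accepted(self):
        overall = overall_accuracy(0.9, 0.8, 0.5, 0.5)
        rep = EvaluationReport(
            stage1_acc=0.9, stage1_sd=0.0, stage2_acc=0.8, stage2_sd=0.0,
            ns_frac=0.5, sc_frac=0.5, overall_acc=overall, protocol="cv5",
        )
        assert rep.to_dict()["overall_acc"] == overall


class TestFitTwoStage:
    def test_stage2_trained_on_exactly_ns_rows(self, small_data, small_model):
        ns_names = [
            small_data.descriptors.row_ids[i]
            for i in range(len(small_data))
            if small_data.top_labels[i] == TopLabel.NS
            and small_data.sub_labels[i] != SubLabel.NONE
        ]
        assert small_model.stage2._train_names == ns_names

    def test_missing_class_rejected(self):
        _, data = generate_hierarchical_dataset(
            SyntheticSpec(n_per_leaf={"AD": 8, "SQ": 8, "SC": 8}, n_dims=20, seed=0)
        )
        no_sq = [i for i in range(len(data)) if data.sub_labels[i] != SubLabel.SQ]
        with pytest.raises(ValidationError, match="SQ"):
            fit_two_stage(data.subset(no_sq), fast_config())

    def test_seeded_fit_deterministic(self, small_data):
        cfg = fast_config(seed=5)
        held_out = small_data.descriptors.select_rows(np.arange(len(small_data)) < 6)
        a, _ = predict_two_stage(fit_two_stage(small_data, cfg, seed=5), held_out)
        b, _ = predict_two_stage(fit_two_stage(small_data, cfg, seed=5), held_out)
        assert a == b


class TestPredictTwoStage:
    def test_labels_are_leaves(self, small_data, small_model):
        pred, traces = predict_two_stage(small_model, small_data.descriptors)
        assert set(pred) <= {"SC", "AD", "SQ"}
        assert len(traces) == len(small_data)

    def test_routing_exactness(self, small_data, small_model):
        pred, traces = predict_two_stage(small_model, small_data.descriptors)
        sc_at_stage1 = sum(t["stage1"] == "SC" for t in traces)
        never_stage2 = sum("stage2" not in t for t in traces)
        assert sc_at_stage1 == never_stage2
        for t in traces:
            if t["stage1"] == "SC":
                assert t["final"] == "SC" and "stage2" not in t
            else:
                assert t["final"] == t["stage2"] and t["final"] in ("AD", "SQ")

    def test_recovery_on_separable_data(self, small_data, small_model):
        pred, _ = predict_two_stage(small_model, small_data.descriptors)
        true = small_data.leaf_labels()
        assert np.mean([p == t for p, t in zip(pred, true)]) >= 0.9


class TestFolds:
    def test_partition_properties(self, rng):
        labels = list(rng.choice(["SC", "AD", "SQ"], size=47))
        while any(labels.count(c) < 5 for c in ("SC", "AD", "SQ")):
            labels = list(rng.choice(["SC", "AD", "SQ"], size=47))
        folds = stratified_fold_indices(labels, 5, seed=3)
        flat = np.concatenate(folds)
        assert len(flat) == 47 and len(set(flat.tolist())) == 47

    def test_stratification_within_one(self, rng):
        labels = ["SC"] * 20 + ["AD"] * 23 + ["SQ"] * 17
        folds = stratified_fold_indices(labels, 5, seed=0)
        for cls in ("SC", "AD", "SQ"):
            counts = [sum(labels[i] == cls for i in f) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_equal_fold_sizes_n80_k5(self):
        labels = ["SC"] * 40 + ["AD"] * 40
        folds = stratified_fold_indices(labels, 5, seed=0)
        assert [len(f) for f in folds] == [16] * 5

    def test_small_class_error_suggests_remedy(self):
        labels = ["SC"] * 3 + ["AD"] * 10
        with pytest.raises(ValidationError, match="smaller k|unstratified"):
            stratified_fold_indices(labels, 5, seed=0)

    def test_unstratified_partition(self):
        labels = ["SC"] * 3 + ["AD"] * 10
        folds = stratified_fold_indices(labels, 5, seed=0, stratified=False)
        assert sorted(np.concatenate(folds).tolist()) == list(range(13))

    def test_seeded_determinism(self):
        labels = ["SC"] * 20 + ["AD"] * 20
        a = stratified_fold_indices(labels, 4, seed=9)
        b = stratified_fold_indices(labels, 4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


@pytest.fixture(scope="module")
def report(shells_data):
    _, data = shells_data
    return cross_validate(data, fast_config(seed=1))


class TestCrossValidate:
    def test_report_fields_consistent(self, report):
        expected = overall_accuracy(
            report.stage1_acc, report.stage2_acc, report.ns_frac, report.sc_frac
        )
        assert report.overall_acc == pytest.approx(expected, abs=1e-9)
        assert report.protocol == "cv5"
        assert len(report.fold_stage1) == 5

    def test_class_fractions_from_dataset(self, report):
        assert report.ns_frac == pytest.approx(90 / 125)
        assert report.sc_frac == pytest.approx(35 / 125)

    def test_recovery(self, report):
        assert report.overall_acc >= 0.9

    def test_fraction_override(self, shells_data):
        _, data = shells_data
        cfg = fast_config(seed=1)
        from dataclasses import replace
        cfg = replace(cfg, eval=replace(cfg.eval, ns_frac_override=0.487, sc_frac_override=0.513))
        rep = cross_validate(data, cfg)
        assert rep.ns_frac == 0.487 and rep.sc_frac == 0.513


class TestEvaluateIndependent:
    def test_train_equals_test_smoke(self, small_data):
        cfg = fast_config(seed=5)
        rep = evaluate_independent(cfg, small_data, small_data)
        assert rep.protocol == "independent"
        assert rep.stage1_acc >= 0.9  # transductive embedding of identical rows

    def test_disjoint_generalization(self):
        spec = SyntheticSpec(n_per_leaf={"AD": 20, "SQ": 20, "SC": 20}, n_dims=60, seed=11)
        _, data = generate_hierarchical_dataset(spec)
        idx = np.arange(len(data))
        train, test = data.subset(idx[idx % 3 != 0]), data.subset(idx[idx % 3 == 0])
        rep = evaluate_independent(fast_config(seed=2), train, test)
        assert rep.overall_acc >= 0.85

    def test_internal_consistency(self, small_data):
        rep = evaluate_independent(fast_config(seed=5), small_data, small_data)
        expected = overall_accuracy(rep.stage1_acc, rep.stage2_acc, rep.ns_frac, rep.sc_frac)
        assert rep.overall_acc == pytest.approx(expected, abs=1e-9)


class TestNaiveBaseline:
    def test_label_flattening(self, small_data):
        leaves = small_data.leaf_labels()
        for i, (top, sub) in enumerate(zip(small_data.top_labels, small_data.sub_labels)):
            if sub != SubLabel.NONE:
                assert leaves[i] == sub.value
            else:
                assert leaves[i] == top.value

    def test_same_splits_as_two_stage(self, small_data):
        labels = small_data.leaf_labels()
        a = stratified_fold_indices(labels, 5, seed=7)
        b = stratified_fold_indices(labels, 5, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_baseline_runs_and_scores(self, small_data):
        mean, sd, folds = cross_validate_naive(small_data, fast_config(seed=5))
        assert 0.0 <= mean <= 1.0 and len(folds) == 5


class TestKnnMapPolicy:
    def test_out_of_sample_without_joint_embedding(self, small_data):
        from dataclasses import replace
        cfg = fast_config(seed=5)
        cfg = replace(
            cfg,
            stage1=replace(cfg.stage1, oos="knn_map"),
            stage2=replace(cfg.stage2, oos="knn_map"),
        )
        idx = np.arange(len(small_data))
        train, test = small_data.subset(idx[idx % 4 != 0]), small_data.subset(idx[idx % 4 == 0])
        model = fit_two_stage(train, cfg, seed=5)  # no oos rows passed
        pred, _ = predict_two_stage(model, test.descriptors)
        true = test.leaf_labels()
        assert np.mean([p == t for p, t in zip(pred, true)]) >= 0.7


class TestPCAStages:
    def test_pca_dimred_both_stages(self, small_data):
        from dataclasses import replace
        cfg = fast_config(seed=5)
        cfg = replace(
            cfg,
            stage1=replace(cfg.stage1, dimred="pca"),
            stage2=replace(cfg.stage2, dimred="pca"),
        )
        rep = cross_validate(small_data, cfg)
        assert 0.0 <= rep.overall_acc <= 1.0
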