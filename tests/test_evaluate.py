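"""Metric conventions, splits, and evaluation protocols."""

import numpy as np
import pytest

from uwbfall.evaluate import (
    FallCounts,
    LosoResult,
    confusion,
    evaluate_predictions,
    fall_counts,
    frames_sweep,
    loso_cv,
    metrics,
    proportional_cell_counts,
    split_dataset,
    subject_id_control,
    transfer_eval,
)
from uwbfall.network import ModelConfig
from uwbfall.preprocess import PreprocessConfig
from uwbfall.radar_sim import (
    FALL_CLASS,
    default_subjects,
    generate_dataset,
    make_scene,
)

FAST_MODEL = dict(
    n_frames=20,
    n_bins=32,
    conv_filters=(2, 2),
    convlstm_hidden=2,
    dense_units=8,
    dropout_rate=0.0,
    l2_penalty=0.0,
    max_epochs=2,
    batch_size=50,
)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = [1, 2, 3, 4, 5, 6, 2, 2]
        mat = confusion(y, y)
        assert np.all(mat == np.diag(np.diag(mat)))
        assert mat.sum() == len(y)

    def test_single_misclassification_lands_off_diagonal(self):
        mat = confusion([2], [3])
        assert mat[1, 2] == 1 and mat.sum() == 1

    def test_total_conserved_at_scale(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 7, 600)
        p = rng.integers(1, 7, 600)
        assert confusion(t, p).sum() == 600

    def test_out_of_range_label_raises(self):
        with pytest.raises(ValueError):
            confusion([0], [1])
        with pytest.raises(ValueError):
            confusion([1], [7])


class TestFallCounts:
    def test_diagonal_matrix_counts(self):
        mat = np.diag([50, 100, 50, 50, 50, 50])
        c = fall_counts(mat, FALL_CLASS)
        assert (c.tp, c.fn, c.fp, c.tn) == (100, 0, 0, 250)

    def test_ninety_five_of_hundred_falls_detected(self):
        mat = np.diag([100, 95, 100, 100, 100, 100])
        mat[1, 0] = 5  # 5 falls missed as standing still
        c = fall_counts(mat, FALL_CLASS)
        m = metrics(c)
        assert (c.tp, c.fn) == (95, 5)
        assert m.sensitivity == pytest.approx(0.95)

    def test_non_fall_error_between_non_fall_classes_affects_neither_tn_nor_fp(self):
        base = np.diag([100, 100, 100, 100, 100, 100])
        shuffled = base.copy()
        shuffled[2, 2] -= 10
        shuffled[2, 3] += 10  # lying mistaken for standing up
        c0, c1 = fall_counts(base), fall_counts(shuffled)
        assert c1.fp == c0.fp == 0
        assert c1.tn == c0.tn - 10  # those samples leave the TN pool...
        m0, m1 = metrics(c0), metrics(c1)
        assert m1.sensitivity == m0.sensitivity  # ...without touching sensitivity
        # they also leave the accuracy denominator, so fall-convention
        # accuracy is untouched while plain multiclass accuracy drops
        assert m1.accuracy == m0.accuracy == 1.0


class TestMetrics:
    def test_all_half_counts(self):
        m = metrics(FallCounts(tp=1, fp=1, tn=1, fn=1))
        assert m.accuracy == m.sensitivity == m.specificity == 0.5

    def test_all_correct(self):
        m = metrics(FallCounts(tp=10, fp=0, tn=50, fn=0))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_zero_denominator_is_flagged_not_silently_zero(self):
        m = metrics(FallCounts(tp=0, fp=0, tn=0, fn=0))
        assert "sensitivity" in m.undefined
        assert np.isnan(m.sensitivity)


class TestSplitDataset:
    def test_campaign_layout_sizes(self, tiny_dataset):
        per_cell = {"train": 2, "val": 1, "test": 1}
        tr, va, te = split_dataset(tiny_dataset, per_cell, seed=4)
        cells = 2 * 6  # subjects x activities
        assert (len(tr), len(va), len(te)) == (2 * cells, cells, cells)

    def test_disjoint_and_seeded(self, tiny_dataset):
        per_cell = {"train": 2, "val": 1, "test": 1}
        a = split_dataset(tiny_dataset, per_cell, seed=4)
        b = split_dataset(tiny_dataset, per_cell, seed=4)
        ids = lambda split: {id(x) for x in split}
        assert ids(a[0]) == ids(b[0]) and ids(a[2]) == ids(b[2])
        assert not (ids(a[0]) & ids(a[1])) and not (ids(a[1]) & ids(a[2]))

    def test_insufficient_cell_raises(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_dataset(tiny_dataset, {"train": 62, "val": 20, "test": 20}, seed=0)

    def test_proportional_counts_reproduce_campaign_ratios(self):
        assert proportional_cell_counts(102) == {"train": 62, "val": 20, "test": 20}


@pytest.fixture(scope="module")
def protocol_dataset():
    """2 subjects x 6 x 8 at 32 bins: enough for protocol structure tests."""
    pulse = make_scene("lab").pulse.with_bins(32)
    scene = make_scene("lab", pulse=pulse, seed=2, noise_sigma=0.02)
    return generate_dataset(scene, default_subjects(2, seed=2), 8, seed=2)


@pytest.fixture(scope="module")
def pcfg():
    return PreprocessConfig(n_bins=32)


class TestLosoCv:
    def test_folds_have_disjoint_subjects_and_pool_conserves_counts(self, protocol_dataset, pcfg):
        cfg = ModelConfig(seed=1, **FAST_MODEL)
        result = loso_cv(protocol_dataset, pcfg, cfg, seed=1, augment=False)
        assert isinstance(result, LosoResult)
        assert len(result.folds) == 2
        subjects = [f.metadata["test_subject"] for f in result.folds]
        assert len(set(subjects)) == 2
        per_subject = len(protocol_dataset) // 2
        for fold in result.folds:
            assert fold.confusion.sum() == per_subject
        assert result.pooled.confusion.sum() == len(protocol_dataset)

    def test_single_subject_raises(self, protocol_dataset, pcfg):
        solo = [r for r in protocol_dataset if r.subject_id == "S1"]
        with pytest.raises(ValueError):
            loso_cv(solo, pcfg, ModelConfig(seed=0, **FAST_MODEL), seed=0)


@pytest.fixture(scope="module")
def lab_model(protocol_dataset, pcfg):
    from uwbfall.evaluate import _fit_and_eval

    tr, va, te = split_dataset(protocol_dataset, {"train": 5, "val": 2, "test": 1}, seed=3)
    _, model = _fit_and_eval(
        tr, va, te, pcfg, ModelConfig(seed=3, **FAST_MODEL), seed=3, metadata={}, augment=False
    )
    return model


class TestTransferEval:

    def test_report_tagged_with_both_environments(self, lab_model, pcfg):
        pulse = make_scene("lounge").pulse.with_bins(32)
        lounge = make_scene("lounge", pulse=pulse, seed=5, noise_sigma=0.02)
        target = generate_dataset(lounge, default_subjects(1, seed=5), 2, seed=5)
        report = transfer_eval(lab_model, target, pcfg)
        assert report.metadata["train_environment"] == "lab"
        assert report.metadata["test_environment"] == "lounge"
        assert report.confusion.sum() == len(target)

    def test_empty_target_raises_and_same_env_warns(self, lab_model, protocol_dataset, pcfg):
        with pytest.raises(ValueError):
            transfer_eval(lab_model, [], pcfg)
        with pytest.warns(UserWarning):
            transfer_eval(lab_model, protocol_dataset[:6], pcfg)


class TestFramesSweep:
    def test_one_report_per_count_with_trimmed_inputs(self, protocol_dataset, pcfg):
        cfg = ModelConfig(seed=4, **FAST_MODEL)
        out = frames_sweep(
            protocol_dataset,
            [8, 20],
            pcfg,
            cfg,
            seed=4,
            per_cell={"train": 5, "val": 2, "test": 1},
            augment=False,
        )
        assert sorted(out) == [8, 20]
        for count, report in out.items():
            assert report.metadata["frames"] == count

    def test_invalid_count_raises(self, protocol_dataset, pcfg):
        with pytest.raises(ValueError):
            frames_sweep(protocol_dataset, [25], pcfg, ModelConfig(**FAST_MODEL), seed=0)


class TestSubjectIdControl:
    def test_chance_level_and_report_shape(self, protocol_dataset, pcfg):
        cfg = ModelConfig(seed=5, **FAST_MODEL)
        result = subject_id_control(
            protocol_dataset, pcfg, cfg, seed=5, per_cell={"train": 5, "val": 2, "test": 1}, augment=False
        )
        assert result.n_subjects == 2
        assert result.chance_level == pytest.approx(0.5)
        assert 0.0 <= result.accuracy <= 1.0
        assert result.confusion.shape == (2, 2)

    def test_single_subject_raises(self, protocol_dataset, pcfg):
        solo = [r for r in protocol_dataset if r.subject_id == "S1"]
        with pytest.raises(ValueError):
            subject_id_control(solo, pcfg, ModelConfig(**FAST_MODEL), seed=0)


class TestEvaluatePredictions:
    def test_metrics_within_bounds_and_metadata_kept(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 7, 200)
        p = rng.integers(1, 7, 200)
        rep = evaluate_predictions(t, p, metadata={"protocol": "x"})
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.multiclass_accuracy):
            assert 0.0 <= v <= 1.0
        assert rep.metadata["protocol"] == "x"
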