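"""Prediction-matrix assembly, the fusion network, and comparator ensembles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ctrecur import nn
from ctrecur.ensemble import (
    assemble_predictions,
    build_fusion_net,
    classical_ensemble,
    fusion_predict,
    majority_vote,
    parse_combo,
    train_fusion,
)
from ctrecur.evaluate import (Hyperparams, make_folds, match_fusion_steps,
                              quick_hyperparams, roc_auc)


def _pm(values, labels, names=None):
    values = np.asarray(values)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    ids = [f"P{i}" for i in range(values.shape[0])]
    return assemble_predictions({n: values[:, j] for j, n in enumerate(names)},
                                ids, labels, order=names)


class TestCombos:
    def test_three_slices_plus_two_kernels(self):
        assert parse_combo("3slices+5/6") == [
            "first_before", "medium", "first_after", "kernel5", "kernel6"]

    @pytest.mark.parametrize("combo,expected", [
        ("5slices", ["second_before", "first_before", "medium",
                     "first_after", "second_after"]),
        ("2/4/6", ["kernel2", "kernel4", "kernel6"]),
        ("50,100,150", ["scale50", "medium", "scale150"]),
        ("3slices+50,150", ["first_before", "medium", "first_after",
                            "scale50", "scale150"]),
    ])
    def test_vocabulary(self, combo, expected):
        assert parse_combo(combo) == expected

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            parse_combo("medium")


class TestAssemble:
    def test_matrix_shape_and_order(self, rng):
        cols = {f"m{j}": rng.random(10) for j in range(3)}
        pm = assemble_predictions(cols, [f"P{i}" for i in range(10)],
                                  rng.integers(0, 2, 10))
        assert pm.values.shape == (10, 3)
        assert pm.model_names == ["m0", "m1", "m2"]

    def test_duplicate_patient_id_rejected(self, rng):
        cols = {"a": rng.random(3), "b": rng.random(3)}
        with pytest.raises(ValueError, match="unique"):
            assemble_predictions(cols, ["P1", "P1", "P2"], [0, 1, 0])

    def test_length_mismatch_and_missing_column(self, rng):
        with pytest.raises(ValueError, match="length"):
            assemble_predictions({"a": rng.random(4), "b": rng.random(3)},
                                 list("wxyz"), [0, 1, 0, 1])
        with pytest.raises(KeyError):
            assemble_predictions({"a": rng.random(3)}, list("xyz"), [0, 1, 0],
                                 order=["a", "zz"])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            _pm([[0.5, 1.2], [0.1, 0.2]], [0, 1])


class TestFusionNet:
    def test_layer_widths_16_32_64_16_1(self):
        fnet = build_fusion_net(4, seed=0)
        linears = [l for l in fnet.net.layers if isinstance(l, nn.Linear)]
        dims = [(l.weight.value.shape[1], l.weight.value.shape[0]) for l in linears]
        assert dims == [(4, 16), (16, 32), (32, 64), (64, 16), (16, 1)]

    @pytest.mark.parametrize("k,expected", [(3, 3781), (5, 3813)])
    def test_parameter_counts(self, k, expected):
        assert build_fusion_net(k, seed=0).trainable_parameter_count == expected

    def test_output_is_probability(self, rng):
        fnet = build_fusion_net(3, seed=1)
        out = fusion_predict(fnet, rng.random((20, 3)))
        assert ((out > 0) & (out < 1)).all()

    def test_too_few_models_rejected(self):
        with pytest.raises(ValueError):
            build_fusion_net(1, seed=0)


class TestTrainFusion:
    def test_learns_identity_column(self):
        """A column that already equals the label must be exploitable to >= 95%
        held-out accuracy for seeds {0, 1, 2}."""
        rng = np.random.default_rng(0)
        n = 50
        labels = np.arange(n) % 2
        values = np.column_stack([labels.astype(float), rng.random(n), rng.random(n)])
        pm = _pm(values, labels)
        folds = make_folds(labels, seed=0, patient_ids=pm.patient_ids)
        hp = match_fusion_steps(Hyperparams(), 40)  # step-matched protocol
        for seed in (0, 1, 2):
            result = train_fusion(pm, folds, hp=hp, seed=seed)
            acc = np.mean((result.oof >= 0.5) == labels)
            assert acc >= 0.95, f"seed {seed}: {acc}"

    def test_pure_noise_gives_chance_auc(self):
        rng = np.random.default_rng(42)
        n = 100
        labels = np.arange(n) % 2
        pm = _pm(rng.random((n, 3)), labels)
        folds = make_folds(labels, seed=0, patient_ids=pm.patient_ids)
        result = train_fusion(pm, folds, hp=match_fusion_steps(Hyperparams(), 80),
                              seed=0)
        assert 0.35 <= roc_auc(labels, result.oof) <= 0.65

    def test_out_of_fold_bookkeeping(self, rng):
        n = 30
        labels = np.arange(n) % 2
        pm = _pm(rng.random((n, 3)), labels)
        folds = make_folds(labels, seed=3, patient_ids=pm.patient_ids)
        result = train_fusion(pm, folds, hp=quick_hyperparams(5, 20), seed=0)
        assert np.isfinite(result.oof).all()  # exactly one prediction each
        for f, test_ids in enumerate(result.test_ids):
            for pid in test_ids:
                assert pid not in result.train_ids[f]
                assert folds.fold_of(pid) == f

    def test_fold_mismatch_rejected(self, rng):
        labels = np.arange(10) % 2
        pm = _pm(rng.random((10, 2)), labels)
        folds = make_folds(labels, seed=0, patient_ids=[f"Q{i}" for i in range(10)])
        with pytest.raises(ValueError, match="missing"):
            train_fusion(pm, folds)


class TestMajorityVote:
    def test_strict_majority_and_binarized_votes(self):
        pm = _pm([[0.9, 0.8, 0.2], [0.6, 0.4, 0.3]], [1, 0])
        np.testing.assert_array_equal(majority_vote(pm), [1, 0])

    def test_tie_broken_by_mean_probability(self):
        pm = _pm([[0.8, 0.3], [0.6, 0.2]], [1, 0])
        # votes (1,0) both rows; means 0.55 -> 1 and 0.40 -> 0
        np.testing.assert_array_equal(majority_vote(pm), [1, 0])


class TestClassicalEnsembles:
    def test_lr_separates_label_column(self):
        n = 40
        labels = np.arange(n) % 2
        rng = np.random.default_rng(1)
        values = np.column_stack([labels.astype(float), rng.random(n)])
        pm = _pm(values, labels)
        folds = make_folds(labels, seed=0, patient_ids=pm.patient_ids)
        oof = classical_ensemble(pm, folds, "LR")
        assert np.mean((oof >= 0.5) == labels) >= 0.95

    def test_all_methods_output_probabilities_deterministically(self, rng):
        n = 30
        labels = np.arange(n) % 2
        pm = _pm(rng.random((n, 3)), labels)
        folds = make_folds(labels, seed=0, patient_ids=pm.patient_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # QDA may warn on collinearity
            for method in ("RF", "LR", "SVM", "GB", "GNB", "LDA", "QDA"):
                a = classical_ensemble(pm, folds, method, seed=11)
                b = classical_ensemble(pm, folds, method, seed=11)
                assert a.min() >= 0 and a.max() <= 1
                np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, rng):
        labels = np.arange(10) % 2
        pm = _pm(rng.random((10, 2)), labels)
        folds = make_folds(labels, seed=0, patient_ids=pm.patient_ids)
        with pytest.raises(ValueError):
            classical_ensemble(pm, folds, "MLP")
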