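"""Loss, trainer, protocols, baselines and leakage audit."""

import numpy as np
import pytest

from eegpf._autodiff import Tensor
from eegpf.evaluation import (METHODS, FeatureDataset, PrepConfig, TrainConfig,
                              _fit_predict, attention_report,
                              cross_entropy_loss, evaluate_kfold,
                              evaluate_loso, featurize_dataset,
                              results_table, run_experiment_grid, train_model)
from eegpf.network import ModelConfig


@pytest.fixture(scope="module")
def fdata(small_dataset):
    return featurize_dataset(small_dataset.recordings,
                             small_dataset.personalities,
                             small_dataset.ratings)


@pytest.fixture(scope="module")
def fast_train():
    return TrainConfig(epochs=6, batch_size=128, lr=0.02, patience=6, seed=0)


@pytest.fixture(scope="module")
def small_net(fdata):
    return ModelConfig(n_bands=fdata.n_bands, n_channels=fdata.n_channels,
                       n_segments=fdata.n_segments, d_embed=6, d_attn=6,
                       u_spatial=6, k_compress=3, v_temporal=8, seed=0)


class TestCrossEntropyLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            # the 0 at the wrong class is irrelevant; picked prob is 1 -> loss 0
            loss = cross_entropy_loss(np.array([[0.0, 1.0]]), [0])
        assert cross_entropy_loss(probs, [0]).data == pytest.approx(0.0)

    def test_uniform_binary_is_ln2(self):
        loss = cross_entropy_loss(np.array([[0.5, 0.5]]), [1])
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-12)

    def test_batch_mean(self):
        probs = np.array([[1.0, 0.0], [0.5, 0.5]])
        loss = cross_entropy_loss(probs, [0, 0])
        assert float(loss.data) == pytest.approx(np.log(2) / 2, abs=1e-9)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            loss = cross_entropy_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(loss.data)

    def test_gradient_flows(self):
        from eegpf._autodiff import backward
        logits = Tensor(np.array([[0.3, -0.2]]), requires_grad=True)
        loss = cross_entropy_loss(logits.softmax(axis=-1), [0])
        backward(loss)
        assert np.abs(logits.grad).max() > 0


class TestTrainModel:
    def test_overfits_separable_samples(self, fdata, small_net):
        samples = [s for s in fdata.samples if s.subject_id in ("S00", "S01")][:40]
        from eegpf.evaluation import _stack_samples, _train_threshold
        thr = _train_threshold(samples, "valence")
        X, y = _stack_samples(samples, "valence", thr)
        tc = TrainConfig(epochs=40, batch_size=64, lr=0.02, patience=40, seed=0)
        params, trace = train_model(X, y, tc, small_net)
        from eegpf.network import predict_proba
        acc = np.mean(predict_proba(X, params, small_net).argmax(axis=1) == y)
        assert acc >= 0.95
        assert trace[-1] < trace[0]

    def test_single_class_rejected(self, small_net, fast_train, rng):
        X = rng.standard_normal((6, 5, 8, 9))
        with pytest.raises(ValueError, match="single class"):
            train_model(X, np.zeros(6, int), fast_train, small_net)

    def test_deterministic_given_seed(self, small_net, fast_train, rng):
        X = rng.standard_normal((10, 5, 8, 9))
        y = np.array([0, 1] * 5)
        tc = TrainConfig(epochs=3, batch_size=4, lr=0.01, patience=3, seed=9)
        p1, t1 = train_model(X, y, tc, small_net)
        p2, t2 = train_model(X, y, tc, small_net)
        assert t1 == t2
        for k in p1:
            np.testing.assert_array_equal(p1[k].data, p2[k].data)


class TestKfold:
    def test_fold_partition_properties(self, fdata, fast_train, small_net):
        res = evaluate_kfold(fdata, "valence", "svm", k=10,
                             train_config=fast_train, model_config=small_net,
                             seed=0)
        assert res.protocol == "kfold"
        assert len(res.fold_accuracies) == 10
        assert res.n_test == len(fdata.samples)  # every sample tested once
        assert 0.0 <= res.mean_accuracy <= 1.0
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_fold_sizes_differ_by_at_most_one(self, fdata):
        n, k = len(fdata.samples), 10
        rng = np.random.default_rng(0)
        sizes = [len(p) for p in np.array_split(rng.permutation(n), k)]
        assert max(sizes) - min(sizes) <= 1

    def test_k_larger_than_samples_rejected(self, fdata, fast_train, small_net):
        with pytest.raises(ValueError):
            evaluate_kfold(fdata, "valence", "svm", k=10 ** 6,
                           train_config=fast_train, model_config=small_net)

    def test_pf_reports_per_cluster(self, fdata, fast_train, small_net):
        res = evaluate_kfold(fdata, "valence", "gbt", k=4, pf=True, n_clusters=3,
                             train_config=fast_train, model_config=small_net,
                             seed=0)
        assert res.per_cluster is not None
        assert set(res.per_cluster) <= {0, 1, 2}


class TestLoso:
    def test_rounds_equal_subjects(self, fdata, fast_train, small_net):
        res = evaluate_loso(fdata, "valence", "svm", train_config=fast_train,
                            model_config=small_net, seed=0)
        assert len(res.fold_accuracies) == len(fdata.subject_ids)

    def test_pf_routes_and_reports_clusters(self, fdata, fast_train, small_net):
        res = evaluate_loso(fdata, "valence", "gbt", pf=True, n_clusters=3,
                            train_config=fast_train, model_config=small_net,
                            seed=0)
        assert res.per_cluster is not None
        assert sum(len([1]) for _ in res.fold_accuracies) == 15

    def test_leakage_audit_corrupting_test_labels_changes_nothing(
            self, small_dataset, fast_train, small_net):
        """Training artifacts must not depend on held-out ratings."""
        held_out = "S00"
        fd1 = featurize_dataset(small_dataset.recordings,
                                small_dataset.personalities,
                                small_dataset.ratings)
        corrupted = dict(small_dataset.ratings)
        for (sid, k) in corrupted:
            if sid == held_out:
                corrupted[(sid, k)] = (3.0, 6.0)  # garbage test ratings
        fd2 = featurize_dataset(small_dataset.recordings,
                                small_dataset.personalities, corrupted)
        train1 = [s for s in fd1.samples if s.subject_id != held_out]
        train2 = [s for s in fd2.samples if s.subject_id != held_out]
        test1 = [s for s in fd1.samples if s.subject_id == held_out]
        test2 = [s for s in fd2.samples if s.subject_id == held_out]
        tc = TrainConfig(epochs=2, batch_size=128, lr=0.02, patience=2, seed=0)
        _, _, art1 = _fit_predict("net", train1, test1, "valence", tc, small_net)
        _, _, art2 = _fit_predict("net", train2, test2, "valence", tc, small_net)
        assert art1["threshold"] == art2["threshold"]
        for k in art1["params"]:
            np.testing.assert_array_equal(art1["params"][k].data,
                                          art2["params"][k].data)


class TestBaselinesAndGrid:
    def test_identical_split_seeds_identical_test_sets(self, fdata, fast_train,
                                                       small_net):
        r1 = evaluate_kfold(fdata, "valence", "svm", k=5,
                            train_config=fast_train, model_config=small_net,
                            seed=3)
        r2 = evaluate_kfold(fdata, "valence", "gbt", k=5,
                            train_config=fast_train, model_config=small_net,
                            seed=3)
        assert r1.n_test == r2.n_test  # same partition by construction (seeded)

    def test_grid_accounting_and_failure_isolation(self, fdata, fast_train,
                                                   small_net):
        results = run_experiment_grid(
            fdata, "loso", methods=("svm", "nosuch"), pf_modes=(False,),
            axes=("valence",), train_config=fast_train,
            model_config=small_net, seed=0)
        assert len(results) == 2
        errors = [r for r in results if isinstance(r, dict)]
        assert len(errors) == 1 and "nosuch" in errors[0]["error"]

    def test_results_table_shape(self, fdata, fast_train, small_net):
        results = run_experiment_grid(
            fdata, "loso", methods=("svm", "gbt"), pf_modes=(False, True),
            axes=("valence", "arousal"), n_clusters=3,
            train_config=fast_train, model_config=small_net, seed=0)
        table = results_table(results)
        assert table.shape == (2, 8)  # axes x (noPF/PF x 4 methods)
        assert ("noPF", "svm") in table.columns and ("PF", "net") in table.columns

    def test_methods_tuple_matches_table_layout(self):
        assert METHODS == ("svm", "gbt", "net_noattn", "net")


class TestAttentionReport:
    def test_report_contract(self, fdata, fast_train, small_net):
        res = evaluate_loso(fdata, "valence", "net", pf=True, n_clusters=3,
                            train_config=fast_train, model_config=small_net,
                            seed=0, collect_models=True)
        models = [m for m in res.models if m["cluster"] is not None]
        probes = {m["cluster"]: fdata.samples[:4] for m in models}
        report = attention_report(models, probes)
        assert report
        M = fdata.n_channels
        for entry in report.values():
            assert entry["mean_W"].shape == (M, M)
            np.testing.assert_allclose(entry["mean_W"].sum(axis=0), 1.0, atol=1e-6)
            assert entry["importance"].shape == (M,)

    def test_no_attention_models_rejected(self, fdata, fast_train, small_net):
        res = evaluate_loso(fdata, "valence", "net_noattn", pf=True, n_clusters=3,
                            train_config=fast_train, model_config=small_net,
                            seed=0, collect_models=True)
        models = [m for m in res.models if m["cluster"] is not None]
        with pytest.raises(ValueError, match="no-attention"):
            attention_report(models, {models[0]["cluster"]: fdata.samples[:2]})


def test_featurize_counts(small_dataset, fdata):
    # 18 s at 32 Hz -> 18 one-second units -> 2 samples per trial
    assert len(fdata.samples) == len(small_dataset.recordings) * 2
    assert fdata.n_bands == 5 and fdata.n_channels == 8 and fdata.n_segments == 9
    for s in fdata.samples:
        assert s.X.shape == (5, 8, 9)
        assert np.all(np.isfinite(s.X))
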