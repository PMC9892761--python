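import numpy as np
import pytest

from xfnirs import nn, windowing
from xfnirs.models import (
    ConfusionCounts,
    ModelSpec,
    TrainConfig,
    TrainedModel,
    TrainingError,
    build_model,
    compute_metrics,
    cross_validate,
    flatten_length,
    load_model,
    save_model,
    train_model,
)


def toy_dataset(n=200, ws=8, nf=2, seed=0, separable=True):
    """Linearly separable three-class frames: class = sign bucket of a
    linear functional of the channel means."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((int(n * 1.5), ws, nf))
    score = x[:, :, 0].mean(axis=1) - x[:, :, 1].mean(axis=1)
    if separable:
        # keep a margin around the decision boundaries so a perfect linear
        # solution exists
        keep = (np.abs(score) > 0.45) | (np.abs(score) < 0.25)
        x, score = x[keep][:n], score[keep][:n]
        labels = np.where(
            score > 0.45, "left", np.where(score < -0.45, "right", "rest")
        )
    else:
        x = x[:n]
        labels = rng.choice(["left", "right", "rest"], size=n)
    n = len(x)
    return windowing.WindowedDataset(
        frames=x,
        labels=np.array(labels, dtype=object),
        end_indices=np.arange(n),
        ws=ws,
        n_features=nf,
        m_samples=n,
        sampling_rate_hz=10.0,
        feature_names=[f"f{i}" for i in range(nf)],
    )


# ---------------------------------------------------------------------------
# architecture


def test_lstm_flatten_length_ws50():
    assert flatten_length(ModelSpec(kind="lstm", ws=50, n_features=26)) == 6000


def test_cnn_same_padding_shapes():
    spec = ModelSpec(kind="cnn", ws=50, n_features=26, conv_padding="same")
    net = build_model(spec)
    assert net.layer_shapes[0] == (50, 32)  # conv keeps 50 steps
    assert flatten_length(spec) == 25 * 32
    assert net.output_shape == (3,)


def test_cnn_valid_padding_shapes():
    spec = ModelSpec(kind="cnn", ws=50, n_features=26, conv_padding="valid")
    net = build_model(spec)
    assert net.layer_shapes[0] == (48, 32)
    assert flatten_length(spec) == 24 * 32


def test_inconsistent_layer_chain_names_layer():
    layers = [nn.Flatten(), nn.Dense(10, 5), nn.Dense(7, 3)]
    with pytest.raises(ValueError, match=r"layer 2 \(Dense\)"):
        nn.Sequential(layers, input_shape=(5, 2))


def test_conv_shorter_than_kernel_rejected():
    with pytest.raises(ValueError, match="Conv1D"):
        nn.Sequential(
            [nn.Conv1D(2, 4, kernel_size=3, padding="valid")], input_shape=(2, 2)
        )


# ---------------------------------------------------------------------------
# prediction contract


@pytest.fixture(scope="module")
def toy_trained():
    ds = toy_dataset()
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    return train_model(None, ds, TrainConfig(epochs=10, seed=0), spec=spec), ds


def test_proba_sums_to_one(toy_trained):
    model, ds = toy_trained
    p = model.predict_proba(ds.frames[:17])
    assert np.all(p >= 0)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_duplicated_frame_identical_rows(toy_trained):
    model, ds = toy_trained
    pair = np.stack([ds.frames[3], ds.frames[3]])
    p = model.predict_proba(pair)
    np.testing.assert_array_equal(p[0], p[1])


def test_zeroed_final_layer_uniform(toy_trained):
    model, ds = toy_trained
    final = model.network.layers[-1]
    saved_w, saved_b = final.W.copy(), final.b.copy()
    try:
        final.W[...] = 0
        final.b[...] = 0
        p = model.predict_proba(ds.frames[:5])
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-7)
    finally:
        final.W[...] = saved_w
        final.b[...] = saved_b


def test_shape_mismatch_rejected(toy_trained):
    model, _ = toy_trained
    with pytest.raises(ValueError, match="frames must be"):
        model.predict_proba(np.zeros((4, 9, 2)))


# ---------------------------------------------------------------------------
# training contract


@pytest.mark.parametrize("kind", ["cnn", "lstm"])
def test_separable_toy_reaches_high_accuracy(kind):
    ds = toy_dataset(n=300)
    spec = ModelSpec(kind=kind, ws=8, n_features=2)
    model = train_model(None, ds, TrainConfig(epochs=30, seed=0), spec=spec)
    # evaluate without dropout: the fitted model separates the training set
    assert (model.predict(ds.frames) == ds.labels).mean() >= 0.99


def test_zero_epochs_is_noop():
    ds = toy_dataset()
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    net = build_model(spec, seed=3)
    before = net.get_weights()
    model = train_model(net, ds, TrainConfig(epochs=0, seed=3), spec=spec)
    for b, a in zip(before, model.network.get_weights(), strict=True):
        np.testing.assert_array_equal(b, a)
    assert model.history["train_loss"] == []


def test_training_determinism():
    ds = toy_dataset()
    val = toy_dataset(seed=9)
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    m1 = train_model(None, ds, TrainConfig(epochs=5, seed=4), spec=spec, val=val)
    m2 = train_model(None, ds, TrainConfig(epochs=5, seed=4), spec=spec, val=val)
    assert m1.history["val_acc"] == m2.history["val_acc"]
    for a, b in zip(
        m1.network.get_weights(), m2.network.get_weights(), strict=True
    ):
        np.testing.assert_array_equal(a, b)


def test_history_lengths_match_epochs():
    ds = toy_dataset()
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    model = train_model(None, ds, TrainConfig(epochs=7, seed=0), spec=spec)
    assert all(len(v) == 7 for v in model.history.values())


def test_training_loss_decreases():
    ds = toy_dataset(n=300)
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    model = train_model(None, ds, TrainConfig(epochs=10, seed=0), spec=spec)
    assert model.history["train_loss"][-1] <= model.history["train_loss"][0]


def test_divergence_raises():
    ds = toy_dataset(n=50)
    ds.frames[0, 0, 0] = np.inf
    spec = ModelSpec(kind="cnn", ws=8, n_features=2)
    with pytest.raises(TrainingError):
        train_model(
            None, ds, TrainConfig(epochs=2, seed=0, batch_size=50), spec=spec
        )


def test_checkpoint_round_trip(tmp_path, toy_trained):
    model, ds = toy_trained
    path = tmp_path / "model.zip"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_allclose(
        back.predict_proba(ds.frames[:10]),
        model.predict_proba(ds.frames[:10]),
        atol=1e-6,
    )
    assert back.spec == model.spec


# ---------------------------------------------------------------------------
# metrics


def test_metrics_all_correct():
    cc = ConfusionCounts(
        matrix=np.diag([5, 7, 9]), class_names=("left", "right", "rest")
    )
    rep = compute_metrics(cc)
    assert rep.accuracy == 1.0
    assert rep.precision_macro == 1.0
    assert rep.recall_macro == 1.0
    assert rep.f1_macro == 1.0


def test_metrics_worked_example():
    # class 0 one-vs-rest: TP=3, FP=1, FN=2, TN=4
    mat = np.array([[3, 2, 0], [1, 2, 0], [0, 0, 2]])
    cc = ConfusionCounts(matrix=mat, class_names=("a", "b", "c"))
    rep = compute_metrics(cc)
    assert rep.per_class["a"]["precision"] == pytest.approx(0.75)
    assert rep.per_class["a"]["recall"] == pytest.approx(0.6)
    assert rep.per_class["a"]["f1"] == pytest.approx(2.0 / 3.0)


def test_metrics_random_matrix_against_oracle(rng):
    mat = rng.integers(0, 20, size=(3, 3))
    cc = ConfusionCounts(matrix=mat, class_names=("a", "b", "c"))
    rep = compute_metrics(cc)
    total = mat.sum()
    assert rep.accuracy == pytest.approx(np.trace(mat) / total)
    for i, name in enumerate(("a", "b", "c")):
        tp = mat[i, i]
        fp = mat[:, i].sum() - tp
        fn = mat[i, :].sum() - tp
        if tp + fp > 0:
            assert rep.per_class[name]["precision"] == pytest.approx(tp / (tp + fp))
        if tp + fn > 0:
            assert rep.per_class[name]["recall"] == pytest.approx(tp / (tp + fn))


def test_metrics_undefined_is_nan_not_zero():
    # no predictions for class c -> precision undefined
    mat = np.array([[5, 1, 0], [1, 5, 0], [2, 2, 0]])
    cc = ConfusionCounts(matrix=mat, class_names=("a", "b", "c"))
    rep = compute_metrics(cc)
    assert np.isnan(rep.per_class["c"]["precision"])
    assert not np.isnan(rep.precision_macro)


def test_macro_recall_equals_accuracy_on_balanced_symmetric():
    # balanced classes, symmetric confusion: accuracy == macro recall
    mat = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])
    cc = ConfusionCounts(matrix=mat, class_names=("a", "b", "c"))
    rep = compute_metrics(cc)
    assert rep.recall_macro == pytest.approx(rep.accuracy)


def test_confusion_from_labels():
    y_true = np.array(["left", "left", "right", "rest"], dtype=object)
    y_pred = np.array(["left", "right", "right", "rest"], dtype=object)
    cc = ConfusionCounts.from_labels(y_true, y_pred)
    assert cc.matrix.sum() == 4
    assert cc.matrix[0, 0] == 1 and cc.matrix[0, 1] == 1
    ovr = cc.one_vs_rest(0)
    assert ovr == {"TP": 1, "FP": 0, "FN": 1, "TN": 2}


# ---------------------------------------------------------------------------
# cross-validation


def _fast_cfg():
    return TrainConfig(epochs=2, seed=0, batch_size=64)


def test_kfold_partition_contract():
    ds = toy_dataset(n=120)
    cv = cross_validate(ds, "cnn", k=10, cfg=_fast_cfg(), seed=0)
    all_idx = np.concatenate(cv.fold_test_indices)
    assert len(all_idx) == 120
    assert len(np.unique(all_idx)) == 120  # disjoint and exhaustive
    assert len(cv.fold_accuracies) == 10


def test_cv_determinism():
    ds = toy_dataset(n=80)
    cv1 = cross_validate(ds, "cnn", k=2, cfg=_fast_cfg(), seed=5)
    cv2 = cross_validate(ds, "cnn", k=2, cfg=_fast_cfg(), seed=5)
    for a, b in zip(cv1.fold_test_indices, cv2.fold_test_indices, strict=True):
        np.testing.assert_array_equal(a, b)
    assert cv1.fold_accuracies == cv2.fold_accuracies


def test_cv_class_too_small():
    ds = toy_dataset(n=60)
    ds.labels[:] = "rest"
    ds.labels[:3] = "left"
    with pytest.raises(ValueError, match="fewer than k"):
        cross_validate(ds, "cnn", k=10, cfg=_fast_cfg(), seed=0)


def test_cv_shuffle_mode_75_25():
    ds = toy_dataset(n=100)
    cv = cross_validate(ds, "cnn", k=3, cfg=_fast_cfg(), seed=0, mode="shuffle")
    assert cv.mode == "shuffle"
    for idx in cv.fold_test_indices:
        assert len(idx) == 25


def test_cv_report_frame():
    ds = toy_dataset(n=60)
    cv = cross_validate(ds, "cnn", k=3, cfg=_fast_cfg(), seed=0)
    df = cv.to_frame()
    assert list(df.columns) == ["fold", "accuracy", "precision", "recall", "f1"]
    assert len(df) == 3
    s = cv.summary()
    assert s["n_folds"] == 3 and not s["permuted"]
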