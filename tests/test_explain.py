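import numpy as np
import pytest
from scipy.stats import spearmanr

from xfnirs import nn
from xfnirs.explain import (
    AttributionTensor,
    UnsupportedModelError,
    channel_relevance,
    deepshap_attribute,
    dependence_data,
    exact_shapley,
    interaction_values,
    model_scores64,
    load_attributions,
    save_attributions,
    select_background,
)
from xfnirs.models import ModelSpec, TrainConfig, TrainedModel, train_model
from xfnirs.windowing import Standardizer, WindowedDataset


def _identity_standardizer(nf):
    s = Standardizer()
    s.mean_ = np.zeros(nf)
    s.std_ = np.ones(nf)
    return s


def _linear_cnn_model(ws, nf, w, seed=0):
    """A 'cnn' TrainedModel that computes pure linear scores W . flatten(x)."""
    net = nn.Sequential(
        [nn.Flatten(), nn.Dense(ws * nf, 3, rng=np.random.default_rng(seed))],
        input_shape=(ws, nf),
    )
    net.layers[1].W[...] = w.astype(nn.DTYPE)
    net.layers[1].b[...] = 0.0
    return TrainedModel(
        spec=ModelSpec(kind="cnn", ws=ws, n_features=nf),
        network=net,
        standardizer=_identity_standardizer(nf),
        config=TrainConfig(epochs=0),
    )


# ---------------------------------------------------------------------------
# background selection


def _plain_ds(n=50, ws=6, nf=4, seed=0):
    rng = np.random.default_rng(seed)
    return WindowedDataset(
        frames=rng.standard_normal((n, ws, nf)),
        labels=np.array(["rest"] * n, dtype=object),
        end_indices=np.arange(n),
        ws=ws,
        n_features=nf,
        m_samples=n,
        sampling_rate_hz=10.0,
        feature_names=[f"ch{i}" for i in range(nf)],
    )


def test_background_distinct_draw():
    ds = _plain_ds(n=100)
    bg = select_background(ds, n=30, seed=0)
    assert bg.count == 30
    assert len(np.unique(bg.indices)) == 30


def test_background_capped_with_warning():
    ds = _plain_ds(n=10)
    with pytest.warns(UserWarning, match="using all"):
        bg = select_background(ds, n=50, seed=0)
    assert bg.count == 10


def test_background_determinism():
    ds = _plain_ds(n=100)
    b1 = select_background(ds, n=20, seed=3)
    b2 = select_background(ds, n=20, seed=3)
    np.testing.assert_array_equal(b1.indices, b2.indices)


def test_background_empty_rejected():
    ds = _plain_ds(n=5)
    ds.frames = ds.frames[:0]
    ds.labels = ds.labels[:0]
    ds.end_indices = ds.end_indices[:0]
    with pytest.raises(ValueError, match="empty"):
        select_background(ds, n=1)


# ---------------------------------------------------------------------------
# deepshap core properties


def test_sample_equals_baseline_zero_phi(tiny_cnn):
    model, ds = tiny_cnn
    bg = select_background(ds, n=1, seed=0)
    attr = deepshap_attribute(model, bg.frames[:1], bg)
    np.testing.assert_allclose(attr.values, 0.0, atol=1e-10)


def test_linear_model_closed_form(rng):
    ws, nf = 5, 3
    w = rng.standard_normal((ws * nf, 3))
    model = _linear_cnn_model(ws, nf, w)
    x = rng.standard_normal((ws, nf))
    b = rng.standard_normal((ws, nf))
    bg = type(select_background(_plain_ds(2, ws, nf), 1, 0))(
        frames=b[None], indices=np.array([0]), seed=0
    )
    attr = deepshap_attribute(model, x[None], bg)
    expected = (x - b).reshape(-1)[:, None] * w  # (ws*nf, 3)
    for c in range(3):
        np.testing.assert_allclose(
            attr.values[c, 0].reshape(-1), expected[:, c], atol=1e-8
        )


def test_linear_model_multi_baseline_mean(rng):
    ws, nf = 4, 2
    w = rng.standard_normal((ws * nf, 3))
    model = _linear_cnn_model(ws, nf, w)
    x = rng.standard_normal((ws, nf))
    bgf = rng.standard_normal((7, ws, nf))
    bg = type(select_background(_plain_ds(2, ws, nf), 1, 0))(
        frames=bgf, indices=np.arange(7), seed=0
    )
    attr = deepshap_attribute(model, x[None], bg)
    expected = (x - bgf.mean(axis=0)).reshape(-1)[:, None] * w
    for c in range(3):
        np.testing.assert_allclose(
            attr.values[c, 0].reshape(-1), expected[:, c], atol=1e-8
        )


def test_efficiency_local_accuracy(tiny_cnn):
    model, ds = tiny_cnn
    bg = select_background(ds, n=25, seed=1)
    samples = ds.frames[50:70]
    attr = deepshap_attribute(model, samples, bg)
    scores = model_scores64(model, samples)  # (n, classes)
    totals = attr.values.sum(axis=(2, 3)).T + attr.base_values[None, :]
    assert np.abs(totals - scores).max() < 1e-4


def test_attribution_tensor_shape(tiny_cnn):
    model, ds = tiny_cnn
    bg = select_background(ds, n=5, seed=0)
    attr = deepshap_attribute(model, ds.frames[:9], bg)
    assert attr.shape == (3, 9, ds.ws, ds.n_features)


def test_lstm_unsupported(fixture_ds):
    ds, _ = fixture_ds
    spec = ModelSpec(kind="lstm", ws=ds.ws, n_features=ds.n_features)
    model = train_model(
        None, ds.subset(np.arange(60)), TrainConfig(epochs=0, seed=0), spec=spec
    )
    bg = select_background(ds, n=2, seed=0)
    with pytest.raises(UnsupportedModelError):
        deepshap_attribute(model, ds.frames[:2], bg)


def test_dummy_channel_zero_relevance(tiny_cnn):
    model, ds = tiny_cnn
    conv = model.network.layers[0]
    saved = conv.W.copy()
    try:
        # zero every kernel row touching channel 3 (layout: k blocks of C)
        w = conv.W.reshape(conv.k, conv.c, conv.f)
        w[:, 3, :] = 0.0
        conv.W[...] = w.reshape(conv.k * conv.c, conv.f)
        bg = select_background(ds, n=10, seed=0)
        attr = deepshap_attribute(
            model, ds.frames[:20], bg, feature_names=ds.feature_names
        )
        rel = channel_relevance(attr)
        for cname in attr.class_names:
            scores = dict(rel.rankings[cname])
            assert scores["ch3"] < 1e-8
    finally:
        conv.W[...] = saved


# ---------------------------------------------------------------------------
# exact enumeration oracle


def test_exact_shapley_symmetry(rng):
    # two identical feature columns in an additive scorer get equal phi
    def f(frames):
        return frames[:, :, 0].sum(axis=1) + frames[:, :, 1].sum(axis=1)

    x = rng.standard_normal((4, 3))
    x[:, 1] = x[:, 0]
    b = np.zeros((4, 3))
    phi = exact_shapley(f, x, b, [[0], [1], [2]])
    assert phi[0] == pytest.approx(phi[1], abs=1e-12)


def test_exact_shapley_dummy(rng):
    def f(frames):
        return frames[:, :, 0].sum(axis=1) ** 2

    x = rng.standard_normal((4, 3))
    b = rng.standard_normal((4, 3))
    phi = exact_shapley(f, x, b, [[0], [1], [2]])
    assert phi[1] == pytest.approx(0.0, abs=1e-12)
    assert phi[2] == pytest.approx(0.0, abs=1e-12)


def test_exact_shapley_efficiency_random_scorer(rng):
    w = rng.standard_normal((5, 5))

    def f(frames):  # nonlinear random scorer
        v = frames.mean(axis=1)
        return np.tanh(v @ w).sum(axis=1)

    x = rng.standard_normal((3, 5))
    b = rng.standard_normal((3, 5))
    groups = [[0], [1], [2], [3], [4]]
    phi = exact_shapley(f, x, b, groups)
    assert phi.sum() + f(b[None])[0] == pytest.approx(f(x[None])[0], abs=1e-10)


def test_exact_shapley_group_limit():
    def f(frames):
        return frames.sum(axis=(1, 2))

    x = np.zeros((2, 16))
    with pytest.raises(ValueError, match="enumeration limit"):
        exact_shapley(f, x, x, [[i] for i in range(16)])


def test_exact_shapley_bad_partition():
    def f(frames):
        return frames.sum(axis=(1, 2))

    x = np.zeros((2, 3))
    with pytest.raises(ValueError, match="partition"):
        exact_shapley(f, x, x, [[0], [1]])


# ---------------------------------------------------------------------------
# interactions


def _prod_scorer(frames):
    return frames[:, :, 0].mean(axis=1) * frames[:, :, 1].mean(axis=1)


def test_interaction_additive_zero(rng):
    def f(frames):
        return np.sin(frames[:, :, 0].mean(axis=1)) + frames[:, :, 1].mean(axis=1) ** 2

    x = rng.standard_normal((4, 2))
    b = rng.standard_normal((4, 2))
    im = interaction_values(f, x, b, [[0], [1]])
    assert im.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_interaction_product_symmetric_nonzero(rng):
    x = 1.0 + rng.random((4, 2))
    b = np.zeros((4, 2))
    im = interaction_values(_prod_scorer, x, b, [[0], [1]])
    assert im.values[0, 1] != 0.0
    assert im.values[0, 1] == im.values[1, 0]


def test_interaction_row_sums_match_shapley(rng):
    w = rng.standard_normal((4, 2))

    def f(frames):
        v = frames.mean(axis=1)
        return (v @ w).prod(axis=1)

    x = rng.standard_normal((3, 4))
    b = rng.standard_normal((3, 4))
    groups = [[0], [1], [2], [3]]
    im = interaction_values(f, x, b, groups)
    phi = exact_shapley(f, x, b, groups)
    np.testing.assert_allclose(im.row_sums, phi, atol=1e-10)
    np.testing.assert_allclose(im.values, im.values.T, atol=0)


# ---------------------------------------------------------------------------
# ranking / beeswarm / dependence


def _toy_attr(rng, n=20, ws=4, nf=3):
    values = np.zeros((2, n, ws, nf))
    values[0, :, :, 1] = rng.standard_normal((n, ws))  # only channel 1 matters
    return AttributionTensor(
        values=values,
        base_values=np.zeros(2),
        class_names=("left", "right"),
        feature_names=["a", "b", "c"],
        sample_values=rng.standard_normal((n, ws, nf)),
    )


def test_relevance_degenerate_tensor(rng):
    attr = _toy_attr(rng)
    rel = channel_relevance(attr, k=2)
    ranked = rel.rankings["left"]
    assert ranked[0][0] == "b"
    assert ranked[1][1] == 0.0 and ranked[2][1] == 0.0
    assert [r[0] for r in ranked[1:]] == ["a", "c"]  # ties broken by name


def test_relevance_scale_invariance(rng):
    attr = _toy_attr(rng)
    rel1 = channel_relevance(attr)
    attr2 = AttributionTensor(
        values=2.0 * attr.values,
        base_values=attr.base_values,
        class_names=attr.class_names,
        feature_names=attr.feature_names,
        sample_values=attr.sample_values,
    )
    rel2 = channel_relevance(attr2)
    for c in attr.class_names:
        assert [r[0] for r in rel1.rankings[c]] == [r[0] for r in rel2.rankings[c]]


def test_relevance_is_permutation(tiny_cnn):
    model, ds = tiny_cnn
    bg = select_background(ds, n=8, seed=0)
    attr = deepshap_attribute(model, ds.frames[:15], bg, feature_names=ds.feature_names)
    rel = channel_relevance(attr, k=2)
    for c in attr.class_names:
        assert sorted(r[0] for r in rel.rankings[c]) == sorted(ds.feature_names)


def test_beeswarm_cardinality(rng):
    attr = _toy_attr(rng, n=20)
    rel = channel_relevance(attr, k=2)
    bee = rel.beeswarm
    assert len(bee) == 2 * 2 * 20  # classes x top-k x samples
    assert set(bee.columns) >= {"class", "rank", "channel", "phi", "feature_value"}


def test_dependence_pairs_and_partner(rng):
    attr = _toy_attr(rng, n=25)
    dep = dependence_data(attr, "b", "left", seed=0)
    assert len(dep.x) == 25 and len(dep.phi) == 25
    assert dep.partner in {"a", "c"}
    df = dep.to_frame()
    assert list(df.columns) == ["feature_value", "phi", "partner"]


def test_dependence_unknown_feature_lists_names(rng):
    attr = _toy_attr(rng)
    with pytest.raises(KeyError, match="valid names"):
        dependence_data(attr, "nope", "left")
    with pytest.raises(KeyError, match="unknown class"):
        dependence_data(attr, "a", "nope")


def test_dependence_constant_feature(rng):
    attr = _toy_attr(rng)
    attr.sample_values[:, :, 1] = 3.14
    dep = dependence_data(attr, "b", "left", seed=0)
    assert np.all(dep.x == 3.14)


def test_attribution_hdf5_round_trip(tmp_path, rng):
    attr = _toy_attr(rng)
    path = tmp_path / "attr.h5"
    save_attributions(attr, path)
    back = load_attributions(path)
    np.testing.assert_array_equal(back.values, attr.values)
    assert back.feature_names == attr.feature_names
    assert back.class_names == attr.class_names


# ---------------------------------------------------------------------------
# deepshap vs exact enumeration


def test_deepshap_matches_exact_shapley_ranking(tiny_cnn):
    model, ds = tiny_cnn
    bg = select_background(ds, n=1, seed=1)
    nf = ds.n_features
    groups = [[i] for i in range(nf)]
    samples = ds.frames[:24]
    attr = deepshap_attribute(model, samples, bg, feature_names=ds.feature_names)
    rel = channel_relevance(attr)
    for class_index in range(3):
        cname = attr.class_names[class_index]
        scores = dict(rel.rankings[cname])
        deep = np.array([scores[f] for f in ds.feature_names])

        def predict(frames, c=class_index):
            return model_scores64(model, frames)[:, c]

        exact = np.mean(
            [
                np.abs(exact_shapley(predict, samples[i], bg.frames[0], groups))
                for i in range(len(samples))
            ],
            axis=0,
        )
        rho = spearmanr(deep, exact).statistic
        assert rho >= 0.9, f"class {class_index}: spearman {rho}"
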