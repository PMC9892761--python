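"""Shapley-value attribution for the trained CNN.

``deepshap_attribute`` back-propagates DeepLIFT rescale-rule multipliers
from each pre-softmax class score to every input cell, for every background
baseline, and averages the per-baseline attributions (DeepSHAP). Each
per-baseline attribution satisfies summation-to-delta exactly up to float
round-off, so the averaged attribution plus the mean background score
recovers the model score (local accuracy).

``exact_shapley`` and ``interaction_values`` enumerate coalitions of a
black-box scorer and serve as the independent oracle for the main path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from xfnirs import nn
from xfnirs.models import TrainedModel
from xfnirs.windowing import WindowedDataset


class UnsupportedModelError(TypeError):
    """The explanation path covers the CNN only."""


# ---------------------------------------------------------------------------
# background selection


@dataclass
class BackgroundSet:
    frames: np.ndarray
    indices: np.ndarray
    seed: int

    @property
    def count(self) -> int:
        return len(self.frames)


def select_background(
    train: WindowedDataset, n: int = 100, seed: int = 0
) -> BackgroundSet:
    """Seeded uniform draw of reference frames, without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    avail = len(train)
    if avail == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if n > avail:
        warnings.warn(
            f"requested {n} background frames but only {avail} available; using all",
            stacklevel=2,
        )
        idx = np.arange(avail)
    else:
        idx = np.sort(rng.choice(avail, size=n, replace=False))
    return BackgroundSet(frames=train.frames[idx], indices=idx, seed=seed)


# ---------------------------------------------------------------------------
# DeepLIFT rescale backprop


@dataclass
class AttributionTensor:
    """phi: (classes, samples, WS, feature-channels) plus per-class base values."""

    values: np.ndarray
    base_values: np.ndarray
    class_names: tuple[str, ...]
    feature_names: list[str]
    sample_values: np.ndarray  # the explained frames, same trailing shape

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributions contain non-finite values")
        if self.values.shape[1:] != self.sample_values.shape:
            raise ValueError("values and sample_values shapes disagree")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _relu_multiplier(dx: np.ndarray, dy: np.ndarray, x_in: np.ndarray) -> np.ndarray:
    # rescale rule: dy/dx; near-zero deltas fall back to the gradient at x
    near = np.abs(dx) < 1e-9
    safe = np.where(near, 1.0, dx)
    return np.where(near, (x_in > 0).astype(float), dy / safe)


def _maxpool_ratio(
    xw: np.ndarray, bw: np.ndarray, pool: int
) -> np.ndarray:
    """Per-window multiplier ratios for max pooling under the rescale rule.

    ``xw``/``bw``: (nb, T_out, pool, C) windows of the sample (broadcast)
    and baselines. The output delta of each window is spread over the
    window's inputs proportionally to |input delta|, which keeps the
    resulting multipliers bounded by 1 (|dy| <= max|dx| <= sum|dx|) while
    guaranteeing sum_i ratio_i * dx_i = dy per window exactly. Routing
    everything to the sample's argmax input instead (the textbook
    formulation) is also complete but produces unbounded dy/dx spikes when
    the argmax input barely differs from the baseline, which swamps the
    channel ranking with noise.
    """
    dx = xw - bw
    dy = xw.max(axis=2) - bw.max(axis=2)  # (nb, T_out, C)
    nz = np.abs(dx) > 1e-12
    absdx = np.abs(dx) * nz
    sum_absdx = absdx.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sum_absdx > 0, absdx / np.maximum(sum_absdx, 1e-300), 0.0)
        ratio = np.where(nz, p * dy[:, :, None, :] / np.where(nz, dx, 1.0), 0.0)
    return ratio


def _deeplift_single(
    net: nn.Sequential, x: np.ndarray, baselines: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Attributions of one frame against each baseline.

    Returns (phi, deltas): phi is (nb, n_classes, WS, N) with per-baseline
    completeness, deltas is (nb, n_classes) = f(x) - f(b).
    """
    nb = len(baselines)
    n_classes = net.output_shape[-1]

    # forward both stacks in float64, caching inputs of every layer
    def _forward(v: np.ndarray) -> list[np.ndarray]:
        acts = [v]
        for layer in net.layers:
            if isinstance(layer, nn.Dropout):
                acts.append(acts[-1])
                continue
            params = [p.astype(np.float64) for p in layer.params()]
            acts.append(_apply64(layer, acts[-1], params))
        return acts

    acts_x = _forward(np.repeat(x[None].astype(np.float64), 1, axis=0))
    acts_b = _forward(baselines.astype(np.float64))
    deltas_out = acts_x[-1][0][None, :] - acts_b[-1]  # (nb, n_classes)

    # multipliers: (nb, n_classes, <layer output shape>)
    m = np.zeros((nb, n_classes, n_classes))
    m[:, np.arange(n_classes), np.arange(n_classes)] = 1.0

    for li in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[li]
        a_x, a_b = acts_x[li][0], acts_b[li]  # input-side activations
        o_x, o_b = acts_x[li + 1][0], acts_b[li + 1]
        if isinstance(layer, nn.Dropout):
            continue
        if isinstance(layer, nn.Dense):
            W = layer.W.astype(np.float64)
            m = m @ W.T
        elif isinstance(layer, nn.Flatten):
            m = m.reshape((nb, n_classes) + a_b.shape[1:])
        elif isinstance(layer, nn.ReLU):
            mult = _relu_multiplier(a_x[None] - a_b, o_x[None] - o_b, a_x[None])
            m = m * mult[:, None]
        elif isinstance(layer, nn.MaxPool1D):
            p = layer.p
            t_in = a_b.shape[1]
            t_out = t_in // p
            xw = np.broadcast_to(
                a_x[None, : t_out * p].reshape(1, t_out, p, -1),
                (nb, t_out, p, a_b.shape[2]),
            )
            bw = a_b[:, : t_out * p].reshape(nb, t_out, p, -1)
            ratio = _maxpool_ratio(xw, bw, p)  # (nb, t_out, p, C)
            m_in = m[:, :, :, None, :] * ratio[:, None]
            m_in = m_in.reshape(nb, n_classes, t_out * p, -1)
            if t_out * p < t_in:
                pad = np.zeros((nb, n_classes, t_in - t_out * p, m_in.shape[-1]))
                m_in = np.concatenate([m_in, pad], axis=2)
            m = m_in
        elif isinstance(layer, nn.Conv1D):
            W = layer.W.astype(np.float64)  # (k*C, F)
            k, c = layer.k, layer.c
            rows = m.reshape(nb * n_classes, m.shape[2], layer.f)
            gcols = (rows @ W.T).reshape(nb * n_classes, -1, k, c)
            t_out = gcols.shape[1]
            t_in = a_b.shape[1]
            if layer.padding == "same":
                left = (k - 1) // 2
                right = k - 1 - left
                gxp = np.zeros((nb * n_classes, t_in + left + right, c))
            else:
                left = 0
                gxp = np.zeros((nb * n_classes, t_in, c))
            for j in range(k):
                gxp[:, j : j + t_out, :] += gcols[:, :, j, :]
            m = gxp[:, left : left + t_in, :].reshape(nb, n_classes, t_in, c)
        else:
            raise UnsupportedModelError(
                f"no rescale rule for layer {type(layer).__name__}"
            )

    dx_in = x[None].astype(np.float64) - baselines.astype(np.float64)
    phi = m * dx_in[:, None]
    return phi, deltas_out


def _apply64(layer: nn.Layer, v: np.ndarray, params: list[np.ndarray]) -> np.ndarray:
    """Eval-mode forward in float64 without touching training caches."""
    if isinstance(layer, nn.Dense):
        W, b = params
        return v @ W + b
    if isinstance(layer, nn.Conv1D):
        W, b = params
        k, c = layer.k, layer.c
        if layer.padding == "same":
            left = (k - 1) // 2
            right = k - 1 - left
            vp = np.pad(v, ((0, 0), (left, right), (0, 0)))
        else:
            vp = v
        win = np.lib.stride_tricks.sliding_window_view(vp, k, axis=1)
        win = np.swapaxes(win, 2, 3).reshape(v.shape[0], -1, k * c)
        return win @ W + b
    if isinstance(layer, nn.MaxPool1D):
        p = layer.p
        t_out = v.shape[1] // p
        return v[:, : t_out * p].reshape(v.shape[0], t_out, p, -1).max(axis=2)
    if isinstance(layer, nn.Flatten):
        return v.reshape(v.shape[0], -1)
    if isinstance(layer, nn.ReLU):
        return np.maximum(v, 0.0)
    raise UnsupportedModelError(f"no rescale rule for layer {type(layer).__name__}")


def deepshap_attribute(
    model: TrainedModel,
    samples: np.ndarray,
    background: BackgroundSet,
    feature_names: list[str] | None = None,
) -> AttributionTensor:
    """DeepSHAP attributions of the CNN's pre-softmax class scores.

    Output ``values`` has shape (classes, samples, WS, feature-channels);
    ``base_values`` is the mean pre-softmax score of the background per
    class. Frames are standardized with the model's training statistics
    before attribution (an affine per-feature map, so per-cell attributions
    are unchanged).
    """
    if model.spec.kind != "cnn":
        raise UnsupportedModelError(
            "only the cnn classifier is supported by the explanation module"
        )
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim == 2:
        samples = samples[None]
    if samples.shape[1:] != background.frames.shape[1:]:
        raise ValueError("samples and background frames must share a shape")

    z_samples = model.standardizer.transform(samples)
    z_bg = model.standardizer.transform(
        np.asarray(background.frames, dtype=np.float64)
    )
    net = model.network
    n_classes = net.output_shape[-1]
    n_samples = len(z_samples)
    ws, n_feat = z_samples.shape[1:]

    values = np.empty((n_classes, n_samples, ws, n_feat))
    for si in range(n_samples):
        phi, _ = _deeplift_single(net, z_samples[si], z_bg)
        values[:, si] = phi.mean(axis=0)

    logits_bg = _forward64_batch(net, z_bg)
    base_values = logits_bg.mean(axis=0)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_feat)]
    if len(feature_names) != n_feat:
        raise ValueError("feature_names length must match the feature axis")
    return AttributionTensor(
        values=values,
        base_values=base_values,
        class_names=model.class_names,
        feature_names=list(feature_names),
        sample_values=samples,
    )


def _forward64_batch(net: nn.Sequential, v: np.ndarray) -> np.ndarray:
    out = v.astype(np.float64)
    for layer in net.layers:
        if isinstance(layer, nn.Dropout):
            continue
        out = _apply64(layer, out, [p.astype(np.float64) for p in layer.params()])
    return out


def model_scores64(model: TrainedModel, frames: np.ndarray) -> np.ndarray:
    """Float64 pre-softmax scores under the same arithmetic as attribution."""
    z = model.standardizer.transform(np.asarray(frames, dtype=np.float64))
    return _forward64_batch(model.network, z)


# ---------------------------------------------------------------------------
# exact enumeration oracles


def _as_groups(groups, n_features: int) -> list[np.ndarray]:
    gs = [np.atleast_1d(np.asarray(g, dtype=int)) for g in groups]
    flat = np.concatenate(gs)
    if sorted(flat.tolist()) != list(range(n_features)):
        raise ValueError("groups must partition the feature-channel axis")
    return gs


def _mask_frames(
    sample: np.ndarray, baseline: np.ndarray, groups: list[np.ndarray],
    coalitions: list[tuple[int, ...]],
) -> np.ndarray:
    frames = np.repeat(baseline[None], len(coalitions), axis=0)
    for fi, coal in enumerate(coalitions):
        for g in coal:
            frames[fi][:, groups[g]] = sample[:, groups[g]]
    return frames


def exact_shapley(
    predict,
    sample: np.ndarray,
    baseline: np.ndarray,
    groups,
) -> np.ndarray:
    """Shapley values of feature-channel groups by full coalition enumeration.

    ``predict`` maps a batch of frames (n, WS, N) to scalar scores (n,).
    Features outside a coalition take baseline values. Limited to 15 groups.
    """
    sample = np.asarray(sample, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    gs = _as_groups(groups, sample.shape[1])
    m = len(gs)
    if m > 15:
        raise ValueError(
            f"{m} groups exceeds the 2^15 enumeration limit; use the sampling"
            " estimator instead"
        )
    coalitions = [
        coal for size in range(m + 1) for coal in combinations(range(m), size)
    ]
    v = np.asarray(
        predict(_mask_frames(sample, baseline, gs, coalitions)), dtype=np.float64
    )
    value = dict(zip(coalitions, v, strict=True))
    phi = np.zeros(m)
    fact = math.factorial
    for g in range(m):
        for coal, val in value.items():
            if g in coal:
                continue
            s = len(coal)
            w = fact(s) * fact(m - s - 1) / fact(m)
            phi[g] += w * (value[tuple(sorted(coal + (g,)))] - val)
    return phi


@dataclass
class InteractionMatrix:
    """Pairwise Shapley interaction values; main effects on the diagonal."""

    values: np.ndarray
    groups: list[np.ndarray] = field(default_factory=list)

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


def interaction_values(
    predict,
    sample: np.ndarray,
    baseline: np.ndarray,
    groups,
) -> InteractionMatrix:
    """Exact Shapley interaction matrix by coalition enumeration.

    Off-diagonal entries weight the pairwise difference
    f(S+{i,j}) - f(S+{i}) - f(S+{j}) + f(S) by |S|!(M-|S|-2)!/(2(M-1)!);
    the diagonal is the Shapley value minus the off-diagonal row sum, so
    rows sum exactly to the per-group Shapley values.
    """
    sample = np.asarray(sample, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    gs = _as_groups(groups, sample.shape[1])
    m = len(gs)
    if m > 10:
        raise ValueError(f"{m} groups exceeds the exact interaction limit of 10")
    coalitions = [
        coal for size in range(m + 1) for coal in combinations(range(m), size)
    ]
    v = np.asarray(
        predict(_mask_frames(sample, baseline, gs, coalitions)), dtype=np.float64
    )
    value = dict(zip(coalitions, v, strict=True))
    fact = math.factorial
    phi_pair = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            acc = 0.0
            for coal, val in value.items():
                if i in coal or j in coal:
                    continue
                s = len(coal)
                w = fact(s) * fact(m - s - 2) / (2.0 * fact(m - 1))
                d = (
                    value[tuple(sorted(coal + (i, j)))]
                    - value[tuple(sorted(coal + (i,)))]
                    - value[tuple(sorted(coal + (j,)))]
                    + val
                )
                acc += w * d
            phi_pair[i, j] = phi_pair[j, i] = acc
    phi = exact_shapley(predict, sample, baseline, groups)
    for i in range(m):
        phi_pair[i, i] = phi[i] - (phi_pair[i].sum() - phi_pair[i, i])
    return InteractionMatrix(values=phi_pair, groups=gs)


# ---------------------------------------------------------------------------
# channel ranking, beeswarm and dependence data


@dataclass
class ChannelRelevance:
    """Per-class channel ranking by mean |phi| plus beeswarm samples."""

    rankings: dict[str, list[tuple[str, float]]]
    beeswarm: pd.DataFrame
    k: int

    def top_channels(self, class_name: str, k: int | None = None) -> list[str]:
        k = k or self.k
        return [name for name, _ in self.rankings[class_name][:k]]


def channel_relevance(attr: AttributionTensor, k: int = 10) -> ChannelRelevance:
    """Rank feature-channels by mean absolute attribution per class.

    Scores average |phi| over explained samples and time; ties break by
    channel name. Beeswarm rows carry the signed per-sample attribution
    (summed over time) and the per-sample feature value (mean over time)
    for the top-k channels of each class.
    """
    if attr.values.size == 0:
        raise ValueError("empty attribution tensor")
    n_classes = attr.values.shape[0]
    scores = np.abs(attr.values).mean(axis=(1, 2))  # (classes, features)
    phi_per_sample = attr.values.sum(axis=2)  # (classes, samples, features)
    feat_per_sample = attr.sample_values.mean(axis=1)  # (samples, features)

    rankings: dict[str, list[tuple[str, float]]] = {}
    rows = []
    for ci in range(n_classes):
        cname = attr.class_names[ci]
        order = sorted(
            range(len(attr.feature_names)),
            key=lambda j: (-scores[ci, j], attr.feature_names[j]),
        )
        rankings[cname] = [
            (attr.feature_names[j], float(scores[ci, j])) for j in order
        ]
        for rank, j in enumerate(order[:k]):
            for si in range(phi_per_sample.shape[1]):
                rows.append(
                    {
                        "class": cname,
                        "rank": rank,
                        "channel": attr.feature_names[j],
                        "sample": si,
                        "phi": phi_per_sample[ci, si, j],
                        "feature_value": feat_per_sample[si, j],
                    }
                )
    return ChannelRelevance(rankings=rankings, beeswarm=pd.DataFrame(rows), k=k)


@dataclass
class DependenceData:
    feature: str
    class_name: str
    x: np.ndarray
    phi: np.ndarray
    partner: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_value": self.x, "phi": self.phi, "partner": self.partner}
        )


def approximate_interaction_strength(
    attr: AttributionTensor,
    class_index: int,
    feature_index: int,
    n_rows: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Sampling estimate of how strongly each other channel modulates the
    chosen channel's attribution.

    Rows are subsampled (seeded), sorted by the chosen channel's value and
    binned; the score for a candidate partner is the mean within-bin
    |correlation| between the partner's value and the chosen channel's phi.
    This data-driven estimator stands in for the pairwise enumeration, which
    is infeasible at 72 channels.
    """
    phi = attr.values[class_index].sum(axis=1)  # (samples, features)
    x = attr.sample_values.mean(axis=1)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)[: min(n_rows, n)]
    phi_j = phi[idx, feature_index]
    xs = x[idx]
    order = np.argsort(xs[:, feature_index], kind="stable")
    phi_j = phi_j[order]
    xs = xs[order]
    n_bins = max(2, min(10, len(order) // 20)) if len(order) >= 40 else 2
    bins = np.array_split(np.arange(len(order)), n_bins)
    n_feat = x.shape[1]
    strength = np.zeros(n_feat)
    for p in range(n_feat):
        if p == feature_index:
            continue
        cs = []
        for b in bins:
            if len(b) < 3:
                continue
            xp = xs[b, p]
            pj = phi_j[b]
            if xp.std() == 0 or pj.std() == 0:
                continue
            cs.append(abs(np.corrcoef(xp, pj)[0, 1]))
        strength[p] = float(np.mean(cs)) if cs else 0.0
    return strength


def dependence_data(
    attr: AttributionTensor,
    feature: str,
    class_name: str,
    seed: int = 0,
) -> DependenceData:
    """(feature value, phi) pairs per explained sample for one channel/class,
    with the most strongly interacting partner channel for coloring."""
    if feature not in attr.feature_names:
        raise KeyError(
            f"unknown feature {feature!r}; valid names: {attr.feature_names}"
        )
    if class_name not in attr.class_names:
        raise KeyError(f"unknown class {class_name!r}")
    ci = list(attr.class_names).index(class_name)
    fi = attr.feature_names.index(feature)
    x = attr.sample_values.mean(axis=1)[:, fi]
    phi = attr.values[ci].sum(axis=1)[:, fi]
    strength = approximate_interaction_strength(attr, ci, fi, seed=seed)
    partner = attr.feature_names[int(strength.argmax())]
    return DependenceData(
        feature=feature, class_name=class_name, x=x, phi=phi, partner=partner
    )


# ---------------------------------------------------------------------------
# exports


def save_attributions(attr: AttributionTensor, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=attr.values)
        f.create_dataset("base_values", data=attr.base_values)
        f.create_dataset("sample_values", data=attr.sample_values)
        f.attrs["class_names"] = list(attr.class_names)
        f.attrs["feature_names"] = list(attr.feature_names)


def load_attributions(path: str | Path) -> AttributionTensor:
    import h5py

    with h5py.File(path, "r") as f:
        return AttributionTensor(
            values=np.asarray(f["values"]),
            base_values=np.asarray(f["base_values"]),
            sample_values=np.asarray(f["sample_values"]),
            class_names=tuple(str(s) for s in f.attrs["class_names"]),
            feature_names=[str(s) for s in f.attrs["feature_names"]],
        )


def rankings_to_csv(rel: ChannelRelevance, path: str | Path) -> None:
    rows = [
        {"class": cname, "rank": r, "channel": name, "mean_relevance": score}
        for cname, ranked in rel.rankings.items()
        for r, (name, score) in enumerate(ranked)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
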