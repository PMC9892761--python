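"""Sliding-window framing and block labeling.

A labeled recording of M samples and N feature-channels is cut into
overlapping (WS x N) frames, one per slide of a single row, giving
M - WS frames at stride 1. Each frame is assigned a block label by one of
two rules: strict majority over the block, or unanimity of the newest
second of samples.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from xfnirs.types import CLASS_NAMES, HemoRecording


@dataclass
class FrameBlock:
    """One (WS x N) window; ``end_index`` is the newest row's sample index."""

    data: np.ndarray
    end_index: int
    label: str | None


@dataclass
class WindowReport:
    total: int
    kept: int
    dropped: int
    dropped_end_indices: list[int] = field(default_factory=list)


@dataclass
class WindowedDataset:
    """Stack of labeled frames, the classifier input.

    ``frames`` is (n_frames, WS, N) with features ordered HbO channels then
    HbR channels; ``labels`` holds one class name per frame and
    ``end_indices`` the source-sample index of each frame's newest row.
    """

    frames: np.ndarray
    labels: np.ndarray
    end_indices: np.ndarray
    ws: int
    n_features: int
    m_samples: int
    sampling_rate_hz: float
    feature_names: list[str]
    class_names: tuple[str, ...] = CLASS_NAMES
    labeling: str = "majority"
    stride: int = 1
    report: WindowReport | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def y(self) -> np.ndarray:
        """Integer labels in ``class_names`` order."""
        lut = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            frames=self.frames[idx],
            labels=self.labels[idx],
            end_indices=self.end_indices[idx],
            ws=self.ws,
            n_features=self.n_features,
            m_samples=self.m_samples,
            sampling_rate_hz=self.sampling_rate_hz,
            feature_names=list(self.feature_names),
            class_names=self.class_names,
            labeling=self.labeling,
            stride=self.stride,
        )

    def class_counts(self) -> dict[str, int]:
        c = Counter(self.labels.tolist())
        return {name: c.get(name, 0) for name in self.class_names}


def label_majority(block_labels: np.ndarray | list) -> str | None:
    """Label occupying strictly more than half the block, else ``None``."""
    block_labels = list(block_labels)
    if not block_labels:
        raise ValueError("empty block")
    label, count = Counter(block_labels).most_common(1)[0]
    return label if count * 2 > len(block_labels) else None


def label_latest_second(block_labels: np.ndarray | list, fs: float) -> str | None:
    """Label agreed by all of the newest ceil(fs) samples, else ``None``."""
    block_labels = list(block_labels)
    k = math.ceil(fs)
    if len(block_labels) < k:
        raise ValueError(f"block shorter than one second ({k} samples)")
    tail = block_labels[-k:]
    return tail[0] if all(l == tail[0] for l in tail) else None


_LABEL_RULES = {"majority", "latest_second"}


def frame_windows(
    hemo: HemoRecording,
    ws: int = 50,
    labeling: str = "majority",
    stride: int = 1,
) -> WindowedDataset:
    """Cut a recording into overlapping labeled frames.

    At stride 1 the frames are the slices ending at samples WS..M-1
    (M - WS frames in total); frames whose rule yields no label are dropped
    from the returned dataset and counted in ``report``.
    """
    if labeling not in _LABEL_RULES:
        raise ValueError(f"labeling must be one of {sorted(_LABEL_RULES)}")
    m = hemo.n_samples
    if ws > m:
        raise ValueError(f"ws={ws} exceeds recording length M={m}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    fs = hemo.sampling_rate_hz
    if labeling == "latest_second" and ws < math.ceil(fs):
        raise ValueError("ws must cover at least one second for latest_second")

    x = hemo.feature_matrix()
    n_features = x.shape[1]
    ends = np.arange(ws, m, stride)
    frames, labels, end_indices, dropped_ends = [], [], [], []
    for e in ends:
        block = x[e - ws + 1 : e + 1]
        block_labels = hemo.labels[e - ws + 1 : e + 1]
        if labeling == "majority":
            lab = label_majority(block_labels)
        else:
            lab = label_latest_second(block_labels, fs)
        if lab is None:
            dropped_ends.append(int(e))
        else:
            frames.append(block)
            labels.append(lab)
            end_indices.append(int(e))

    report = WindowReport(
        total=len(ends),
        kept=len(frames),
        dropped=len(dropped_ends),
        dropped_end_indices=dropped_ends,
    )
    frames_arr = (
        np.stack(frames) if frames else np.empty((0, ws, n_features))
    )
    return WindowedDataset(
        frames=frames_arr,
        labels=np.array(labels, dtype=object),
        end_indices=np.array(end_indices, dtype=np.int64),
        ws=ws,
        n_features=n_features,
        m_samples=m,
        sampling_rate_hz=fs,
        feature_names=hemo.feature_names,
        labeling=labeling,
        stride=stride,
        report=report,
    )


def split_dataset(
    ds: WindowedDataset,
    test_fraction: float = 0.25,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Disjoint, exhaustive train/test split of the frames."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if stratify:
        counts = ds.class_counts()
        thin = [n for n, c in counts.items() if 0 < c < 2]
        if thin:
            raise ValueError(f"classes too small to stratify: {thin}")
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=ds.y if stratify else None,
        shuffle=True,
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def balance_classes(ds: WindowedDataset, seed: int = 0) -> WindowedDataset:
    """Subsample majority classes so every class has the minority count."""
    counts = ds.class_counts()
    present = {n: c for n, c in counts.items() if c > 0}
    n_min = min(present.values())
    rng = np.random.default_rng(seed)
    keep = []
    for name in present:
        idx = np.flatnonzero(ds.labels == name)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return ds.subset(keep)


class Standardizer:
    """Per-feature z-scoring with statistics from the training split."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, frames: np.ndarray) -> "Standardizer":
        self.mean_ = frames.mean(axis=(0, 1))
        std = frames.std(axis=(0, 1))
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, frames: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("fit before transform")
        return (frames - self.mean_) / self.std_

    def fit_transform(self, frames: np.ndarray) -> np.ndarray:
        return self.fit(frames).transform(frames)


def save_windowed(ds: WindowedDataset, path: str | Path) -> None:
    """Serialize frames + labels + provenance to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=ds.frames)
        f.create_dataset(
            "labels", data=np.array([l.encode() for l in ds.labels])
        )
        f.create_dataset("end_indices", data=ds.end_indices)
        f.attrs["ws"] = ds.ws
        f.attrs["n_features"] = ds.n_features
        f.attrs["m_samples"] = ds.m_samples
        f.attrs["sampling_rate_hz"] = ds.sampling_rate_hz
        f.attrs["labeling"] = ds.labeling
        f.attrs["stride"] = ds.stride
        f.attrs["class_names"] = list(ds.class_names)
        f.attrs["feature_names"] = list(ds.feature_names)


def load_windowed(path: str | Path) -> WindowedDataset:
    import h5py

    with h5py.File(path, "r") as f:
        return WindowedDataset(
            frames=np.asarray(f["frames"]),
            labels=np.array([l.decode() for l in f["labels"]], dtype=object),
            end_indices=np.asarray(f["end_indices"]),
            ws=int(f.attrs["ws"]),
            n_features=int(f.attrs["n_features"]),
            m_samples=int(f.attrs["m_samples"]),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            feature_names=[str(s) for s in f.attrs["feature_names"]],
            class_names=tuple(str(s) for s in f.attrs["class_names"]),
            labeling=str(f.attrs["labeling"]),
            stride=int(f.attrs["stride"]),
        )
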