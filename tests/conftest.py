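import numpy as np
import pytest

from xfnirs import models, synthetic, windowing
from xfnirs.types import MontageChannel, RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def montage2():
    return [MontageChannel(name="FC3C3"), MontageChannel(name="FC4C4")]


def make_raw(intensity, fs=10.0, labels=None, montage=None):
    n_t, n_c, _ = intensity.shape
    if montage is None:
        montage = [MontageChannel(name=f"C{i}z{i}") for i in range(n_c)]
    if labels is None:
        labels = np.full(n_t, "rest", dtype=object)
    return RawRecording(
        sampling_rate_hz=fs,
        wavelengths=(750.0, 830.0),
        intensity=intensity,
        montage=montage,
        labels=labels,
    )


@pytest.fixture
def small_raw(rng, montage2):
    intensity = 1.0 + 0.01 * rng.standard_normal((200, 2, 2))
    return make_raw(intensity, montage=montage2)


def quiet_ground_truth(preset="datasetB"):
    gt = synthetic.default_ground_truth(preset)
    gt.noise = synthetic.NoiseSpec(
        cardiac_amp=0, resp_amp=0, mayer_amp=0, drift_amp=0, white_sd=0
    )
    return gt


@pytest.fixture(scope="session")
def fixture_ds():
    """Small windowed, balanced paradigm-B dataset shared by model tests."""
    hemo, gt, _ = synthetic.default_fixture(seed=1, n_trials_per_side=4)
    ds = windowing.frame_windows(hemo, ws=50, labeling="majority", stride=4)
    ds = windowing.balance_classes(ds, seed=1)
    return ds, gt


@pytest.fixture(scope="session")
def tiny_cnn():
    """A small trained CNN (WS=6, 4 feature-channels) with planted channel
    effects of distinct magnitude, shared by the explanation tests."""
    rng = np.random.default_rng(0)
    ws, nf, n = 6, 4, 500
    x = rng.standard_normal((n, ws, nf))
    w_eff = np.array([2.0, -1.2, 0.6, 0.0])
    score = (x.mean(axis=1) * w_eff).sum(axis=1)
    labels = np.where(score > 0.5, "left", np.where(score < -0.5, "right", "rest"))
    ds = windowing.WindowedDataset(
        frames=x,
        labels=np.array(labels, dtype=object),
        end_indices=np.arange(n),
        ws=ws,
        n_features=nf,
        m_samples=n,
        sampling_rate_hz=10.0,
        feature_names=[f"ch{i}" for i in range(nf)],
    )
    spec = models.ModelSpec(kind="cnn", ws=ws, n_features=nf)
    trained = models.train_model(
        None, ds, models.TrainConfig(epochs=50, seed=0), spec=spec
    )
    return trained, ds
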