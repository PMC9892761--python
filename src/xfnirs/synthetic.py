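"""Ground-truthed synthetic fNIRS generator.

Emulates two block paradigms down to raw two-wavelength intensities so the
whole pipeline can be exercised offline: paradigm A alternates 20 s
left/right tasks with 20 s rests at 7.8125 Hz over a 20-channel bilateral
motor montage; paradigm B uses 2 s cue + 10 s task + 15-17 s rest trials at
10 Hz over 36 channels spanning frontal, motor and visual regions.

Class-discriminative channels carry a double-gamma HRF convolved with the
task boxcar in HbO (HbR mirrors negatively at a configurable ratio);
all channels receive cardiac/respiratory/Mayer sinusoids, 1/f-style drift
and white noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.stats import gamma as gamma_dist

from xfnirs.types import (
    DEFAULT_WAVELENGTHS,
    ExtinctionCoefficients,
    HemoRecording,
    MontageChannel,
    RawRecording,
)

# ---------------------------------------------------------------------------
# paradigms


@dataclass
class ParadigmSpec:
    preset: str = "datasetB"
    task_duration_s: float = 10.0
    rest_duration_s: tuple[float, float] = (15.0, 17.0)
    cue_duration_s: float = 2.0
    n_trials_per_side: int = 10
    sampling_rate_hz: float = 10.0
    pre_rest_s: float = 10.0

    def __post_init__(self) -> None:
        if self.task_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("durations and sampling rate must be positive")

    @classmethod
    def dataset_a(cls, n_trials_per_side: int = 5) -> "ParadigmSpec":
        return cls(
            preset="datasetA",
            task_duration_s=20.0,
            rest_duration_s=(20.0, 20.0),
            cue_duration_s=0.0,
            n_trials_per_side=n_trials_per_side,
            sampling_rate_hz=7.8125,
            pre_rest_s=20.0,
        )

    @classmethod
    def dataset_b(cls, n_trials_per_side: int = 10) -> "ParadigmSpec":
        return cls(preset="datasetB", n_trials_per_side=n_trials_per_side)


def make_schedule(
    p: ParadigmSpec, seed: int = 0
) -> tuple[list[dict], np.ndarray]:
    """Alternating left/right trial schedule plus the per-sample label stream.

    Cue periods are unlabeled task-wise (they read "rest" in the stream);
    paradigm-B rest durations are drawn uniformly in the configured range.
    """
    rng = np.random.default_rng(seed)
    lo, hi = p.rest_duration_s
    events: list[dict] = []
    t = p.pre_rest_s
    sides = ["left", "right"] * p.n_trials_per_side
    for side in sides:
        t += p.cue_duration_s
        events.append({"onset_s": t, "duration_s": p.task_duration_s, "label": side})
        t += p.task_duration_s
        t += lo if lo == hi else float(rng.uniform(lo, hi))
    total_s = t
    n = int(round(total_s * p.sampling_rate_hz))
    labels = np.full(n, "rest", dtype=object)
    for ev in events:
        a = int(round(ev["onset_s"] * p.sampling_rate_hz))
        b = int(round((ev["onset_s"] + ev["duration_s"]) * p.sampling_rate_hz))
        labels[a : min(b, n)] = ev["label"]
    return events, labels


# ---------------------------------------------------------------------------
# montages

_FRONTAL_B = [
    "AF3AFz", "AF4AFz", "AF7Fp1", "AF8Fp2", "Fp1Fpz", "Fp2Fpz",
    "AF3Fp1", "AF4Fp2", "AFzFpz",
]
_MOTOR_LEFT_B = [
    "FC5FC3", "FC3FC1", "FC5C5", "FC3C3", "FC1C1", "C5CP5",
    "C3CP3", "C1CP1", "C5C3", "C3C1", "CP5CP3", "CP3CP1",
]
_MOTOR_RIGHT_B = [
    "FC6FC4", "FC4FC2", "FC6C6", "FC4C4", "FC2C2", "C6CP6",
    "C4CP4", "C2CP2", "C6C4", "C4C2", "CP6CP4", "CP4CP2",
]
_VISUAL_B = ["O1Oz", "O2Oz", "POzOz"]

_MOTOR_LEFT_A = [
    "FC3C3", "FC1C1", "C3CP3", "C1CP1", "FC5C5",
    "C5CP5", "FC3C1", "C3C1", "CP3CP1", "C5C3",
]
_MOTOR_RIGHT_A = [
    "FC4C4", "FC2C2", "C4CP4", "C2CP2", "FC6C6",
    "C6CP6", "FC4C2", "C4C2", "CP4CP2", "C6C4",
]


def default_montage(preset: str = "datasetB") -> list[MontageChannel]:
    """20-channel bilateral motor (A) or 36-channel three-region (B) montage."""
    if preset == "datasetA":
        return [
            MontageChannel(name=n, region="motor")
            for n in _MOTOR_LEFT_A + _MOTOR_RIGHT_A
        ]
    if preset == "datasetB":
        chans = [MontageChannel(name=n, region="frontal") for n in _FRONTAL_B]
        chans += [
            MontageChannel(name=n, region="motor")
            for n in _MOTOR_LEFT_B + _MOTOR_RIGHT_B
        ]
        chans += [MontageChannel(name=n, region="visual") for n in _VISUAL_B]
        return chans
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# hemodynamics


def double_gamma_hrf(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF (gamma shapes 6 and 16, undershoot ratio
    1/6; peaks at roughly 5 s with an undershoot near 15 s)."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    peak = gamma_dist.pdf(t, 6.0)
    undershoot = gamma_dist.pdf(t, 16.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass
class NoiseSpec:
    """Amplitudes (uM) of the artifact classes the band-pass targets.

    The slow components (Mayer wave, drift) are kept modest by default:
    they pass the 0.01-0.2 Hz filter and, being unique per time point, give
    an over-parameterized classifier a frame-memorization shortcut that
    masks the planted physiology.
    """

    cardiac_amp: float = 0.12
    cardiac_hz: float = 1.1
    resp_amp: float = 0.08
    resp_hz: float = 0.3
    mayer_amp: float = 0.03
    mayer_hz: float = 0.1
    drift_amp: float = 0.05
    white_sd: float = 0.2


@dataclass
class GroundTruth:
    """Planted effects: class -> {channel name: HbO amplitude in uM}."""

    effects: dict[str, dict[str, float]]
    hbr_ratio: float = 1.0 / 3.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    clean_HbO: np.ndarray | None = None
    regressors: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for cls_name, chans in self.effects.items():
            if not chans:
                raise ValueError(f"class {cls_name!r} has no planted channels")

    def planted_channels(self, cls_name: str) -> list[str]:
        return list(self.effects.get(cls_name, {}))


def default_ground_truth(preset: str = "datasetB") -> GroundTruth:
    """Lateralized activations: each hand drives contralateral motor channels.

    Two planted channels per side. Keeping the discriminative set small and
    the effect amplitudes well above the noise floor lets the classifier's
    channel reliance (and hence the attribution ranking) concentrate on the
    planted channels instead of being diluted across redundant copies.
    """
    if preset == "datasetA":
        return GroundTruth(
            effects={
                "left": {"FC4C4": 2.0, "C4CP4": 1.6},
                "right": {"FC3C3": 2.0, "C3CP3": 1.6},
            }
        )
    return GroundTruth(
        effects={
            "left": {"FC4C4": 2.0, "C4CP4": 1.6},
            "right": {"FC3C3": 2.0, "C3CP3": 1.6},
        }
    )


def _noise(n: int, fs: float, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for amp, f in (
        (spec.cardiac_amp, spec.cardiac_hz),
        (spec.resp_amp, spec.resp_hz),
        (spec.mayer_amp, spec.mayer_hz),
    ):
        if amp > 0 and f < fs / 2:
            sig += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if spec.drift_amp > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk -= np.linspace(walk[0], walk[-1], n)  # detrend endpoints
        denom = np.abs(walk).max() or 1.0
        sig += spec.drift_amp * walk / denom
    if spec.white_sd > 0:
        sig += spec.white_sd * rng.standard_normal(n)
    return sig


def simulate_hemo(
    labels: np.ndarray,
    montage: list[MontageChannel],
    gt: GroundTruth,
    fs: float,
    seed: int = 0,
) -> tuple[HemoRecording, GroundTruth]:
    """Render concentration changes for a label stream.

    HbO(channel) = amplitude * (class boxcar (*) HRF) + noise;
    HbR = -hbr_ratio * clean task component + independent noise.
    Returns the recording and a ground-truth copy holding the clean HbO
    components and the HRF-convolved class regressors for oracle checks.
    """
    if not montage:
        raise ValueError("montage must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(labels)
    hrf = double_gamma_hrf(fs)
    regressors: dict[str, np.ndarray] = {}
    for cls_name in gt.effects:
        boxcar = (labels == cls_name).astype(float)
        reg = np.convolve(boxcar, hrf)[:n]
        regressors[cls_name] = reg

    name_to_idx = {c.name: i for i, c in enumerate(montage)}
    clean = np.zeros((n, len(montage)))
    for cls_name, chans in gt.effects.items():
        for chan_name, amp in chans.items():
            if chan_name not in name_to_idx:
                raise ValueError(f"planted channel {chan_name!r} not in montage")
            clean[:, name_to_idx[chan_name]] += amp * regressors[cls_name]

    hbo = clean.copy()
    hbr = -gt.hbr_ratio * clean
    for ci in range(len(montage)):
        hbo[:, ci] += _noise(n, fs, gt.noise, rng)
        hbr[:, ci] += 0.5 * _noise(n, fs, gt.noise, rng)

    hemo = HemoRecording(
        delta_HbO=hbo,
        delta_HbR=hbr,
        sampling_rate_hz=fs,
        montage=list(montage),
        labels=np.asarray(labels, dtype=object).copy(),
    )
    gt_out = replace(gt, clean_HbO=clean, regressors=regressors)
    return hemo, gt_out


def bandpass_hemo(
    hemo: HemoRecording, low_hz: float = 0.01, high_hz: float = 0.2
) -> HemoRecording:
    """Zero-phase band-pass on already-converted concentration series."""
    sos = butter(4, [low_hz, high_hz], btype="bandpass",
                 fs=hemo.sampling_rate_hz, output="sos")
    return HemoRecording(
        delta_HbO=sosfiltfilt(sos, hemo.delta_HbO, axis=0),
        delta_HbR=sosfiltfilt(sos, hemo.delta_HbR, axis=0),
        sampling_rate_hz=hemo.sampling_rate_hz,
        montage=list(hemo.montage),
        labels=hemo.labels.copy(),
    )


# ---------------------------------------------------------------------------
# inverse Beer-Lambert: concentrations -> raw intensities


def hemo_to_intensity(
    hemo: HemoRecording,
    coeffs: ExtinctionCoefficients | None = None,
    montage: list[MontageChannel] | None = None,
    I0: float | np.ndarray = 1.0,
) -> RawRecording:
    """Invert the concentration conversion:

        dA = l * d * E [dHbO; dHbR] / u,    I(t) = I0 * 10^(-dA)

    with u the coefficient set's ``unit_scale`` (uM concentrations,
    mM^-1 mm^-1 extinction units, mm distances by default).
    """
    if coeffs is None:
        coeffs = ExtinctionCoefficients()
    if montage is None:
        montage = hemo.montage
    I0 = np.broadcast_to(np.asarray(I0, dtype=float), (len(montage), 2))
    if np.any(I0 <= 0):
        raise ValueError("baseline intensities must be positive")
    n_t = hemo.n_samples
    intensity = np.empty((n_t, len(montage), 2))
    for ci, chan in enumerate(montage):
        conc_mM = np.stack(
            [hemo.delta_HbO[:, ci], hemo.delta_HbR[:, ci]], axis=1
        ) / coeffs.unit_scale
        delta_A = chan.distance_mm * coeffs.dpf * (conc_mM @ coeffs.matrix.T)
        intensity[:, ci, :] = I0[ci] * np.power(10.0, -delta_A)
    return RawRecording(
        sampling_rate_hz=hemo.sampling_rate_hz,
        wavelengths=coeffs.wavelengths,
        intensity=intensity,
        montage=list(montage),
        labels=hemo.labels.copy(),
    )


# ---------------------------------------------------------------------------
# fixtures on disk and in memory


def write_fixture(
    raw: RawRecording, stem: str | Path, events: list[dict]
) -> Path:
    """Write the csv+json dialect read by :func:`xfnirs.io_preproc.read_recording`."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(raw.n_samples) / raw.sampling_rate_hz
    cols = {"time": t}
    for ci, chan in enumerate(raw.montage):
        for wi, wl in enumerate(raw.wavelengths):
            cols[f"{chan.name}_{wl:g}"] = raw.intensity[:, ci, wi]
    csv_path = stem.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    with open(str(stem) + ".montage.json", "w") as fh:
        json.dump(
            {
                "sampling_rate_hz": raw.sampling_rate_hz,
                "wavelengths": list(raw.wavelengths),
                "channels": [
                    {
                        "name": c.name,
                        "distance_mm": c.distance_mm,
                        "region": c.region,
                    }
                    for c in raw.montage
                ],
            },
            fh,
            indent=1,
        )
    with open(str(stem) + ".events.json", "w") as fh:
        json.dump(events, fh, indent=1)
    return csv_path


def default_fixture(
    seed: int = 0,
    n_trials_per_side: int = 8,
    preset: str = "datasetB",
    bandpass: bool = True,
) -> tuple[HemoRecording, GroundTruth, list[dict]]:
    """Paradigm-B-like recording (36 channels -> 72 features) with planted
    lateralized activations; the standard input for pipeline-level tests.

    Desk-scale: the trial count is reduced from the full three-session
    protocol so cross-validation of both models stays within a few
    CPU-minutes, and rest intervals are extended to 20-24 s (from the
    paradigm's 15-17 s) so the hemodynamic tail of each task block decays
    before most rest-labeled windows start — without that margin the
    planted channels disagree with the rest labels and the classifier
    drifts toward frame memorization.
    """
    if preset == "datasetA":
        p = ParadigmSpec.dataset_a(n_trials_per_side)
    else:
        p = ParadigmSpec(
            preset="custom",
            task_duration_s=10.0,
            rest_duration_s=(20.0, 24.0),
            cue_duration_s=2.0,
            n_trials_per_side=n_trials_per_side,
            sampling_rate_hz=10.0,
        )
    events, labels = make_schedule(p, seed=seed)
    montage = default_montage(preset)
    gt = default_ground_truth(preset)
    hemo, gt = simulate_hemo(labels, montage, gt, p.sampling_rate_hz, seed=seed)
    if bandpass:
        hemo = bandpass_hemo(hemo)
    return hemo, gt, events
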