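"""Shared domain types for recordings, montages and conversion coefficients."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used everywhere a label axis appears.
CLASS_NAMES = ("left", "right", "rest")

#: Extinction coefficients in mM^-1 mm^-1 (tabulated molar absorptivities
#: scaled to the millimetre path lengths used here), editable per deployment.
DEFAULT_EXTINCTION_TABLE = {
    750.0: {"HbO": 0.0518, "HbR": 0.1405},
    830.0: {"HbO": 0.0974, "HbR": 0.0693},
}

DEFAULT_WAVELENGTHS = (750.0, 830.0)
DEFAULT_DPF = 6.0
DEFAULT_DISTANCE_MM = 30.0


@dataclass(frozen=True)
class MontageChannel:
    """One source-detector pair, named by concatenated 10-20 labels."""

    name: str
    distance_mm: float = DEFAULT_DISTANCE_MM
    source_pos: str | None = None
    detector_pos: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError(f"channel {self.name!r}: distance must be > 0")


def _check_montage(montage: list[MontageChannel]) -> None:
    names = [c.name for c in montage]
    if len(set(names)) != len(names):
        raise ValueError("montage channel names must be unique")


@dataclass
class RawRecording:
    """Per-wavelength optical intensity with montage and a per-sample label stream.

    ``intensity`` has shape (time, channel, wavelength); exactly two
    wavelengths are supported. ``labels`` is an object array of
    "left"/"right"/"rest" with one entry per time sample.
    """

    sampling_rate_hz: float
    wavelengths: tuple[float, float]
    intensity: np.ndarray
    montage: list[MontageChannel]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError(
                "intensity must be (time, channel, wavelength=2), got "
                f"{self.intensity.shape}"
            )
        if self.intensity.shape[0] < 1:
            raise ValueError("time axis must have at least one sample")
        if self.intensity.shape[1] != len(self.montage):
            raise ValueError("channel axis does not match montage length")
        if self.labels.shape[0] != self.intensity.shape[0]:
            raise ValueError("label stream must match the time axis")
        _check_montage(self.montage)

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.montage]


@dataclass
class OpticalDensitySeries:
    """Unitless absorbance changes, same (time, channel, wavelength) layout."""

    delta_A: np.ndarray
    wavelengths: tuple[float, float]
    sampling_rate_hz: float
    montage: list[MontageChannel]
    labels: np.ndarray
    baseline_spec: str = "mean"

    def __post_init__(self) -> None:
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if not np.all(np.isfinite(self.delta_A)):
            raise ValueError("optical density contains non-finite values")


@dataclass
class ExtinctionCoefficients:
    """2x2 extinction matrix [[aHbO(l1), aHbR(l1)], [aHbO(l2), aHbR(l2)]].

    Units default to mM^-1 mm^-1; concentrations are reported in uM, so the
    conversion multiplies the inverted system by 1000.
    """

    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    matrix: np.ndarray | None = None
    dpf: float = DEFAULT_DPF
    units: str = "mM^-1*mm^-1"
    #: concentration scale applied after inversion (1000 -> uM when the
    #: matrix is in mM^-1 mm^-1); set to 1.0 for unit-free coefficient systems
    unit_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.matrix is None:
            try:
                self.matrix = np.array(
                    [
                        [
                            DEFAULT_EXTINCTION_TABLE[w]["HbO"],
                            DEFAULT_EXTINCTION_TABLE[w]["HbR"],
                        ]
                        for w in self.wavelengths
                    ]
                )
            except KeyError as exc:
                raise ValueError(
                    f"no tabulated extinction coefficients for {exc}; "
                    "pass an explicit matrix"
                ) from None
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        if self.dpf <= 0:
            raise ValueError("DPF must be positive")
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("extinction matrix is singular")


@dataclass
class HemoRecording:
    """Hemoglobin concentration changes (uM) per surviving physiological channel."""

    delta_HbO: np.ndarray
    delta_HbR: np.ndarray
    sampling_rate_hz: float
    montage: list[MontageChannel]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.delta_HbO = np.asarray(self.delta_HbO, dtype=float)
        self.delta_HbR = np.asarray(self.delta_HbR, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.delta_HbO.shape != self.delta_HbR.shape:
            raise ValueError("HbO and HbR arrays must share a shape")
        if self.delta_HbO.ndim != 2:
            raise ValueError("expected (time, channel) arrays")
        if self.delta_HbO.shape[1] != len(self.montage):
            raise ValueError("channel axis does not match montage length")
        if self.labels.shape[0] != self.delta_HbO.shape[0]:
            raise ValueError("label stream must match the time axis")
        _check_montage(self.montage)

    @property
    def n_samples(self) -> int:
        return self.delta_HbO.shape[0]

    @property
    def n_channels(self) -> int:
        return self.delta_HbO.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.montage]

    @property
    def feature_names(self) -> list[str]:
        """Classifier feature order: all HbO channels, then all HbR channels."""
        return [f"{c.name}oxy" for c in self.montage] + [
            f"{c.name}deoxy" for c in self.montage
        ]

    def feature_matrix(self) -> np.ndarray:
        """(time, 2*channels) matrix in :attr:`feature_names` order."""
        return np.concatenate([self.delta_HbO, self.delta_HbR], axis=1)


@dataclass
class ChannelQuality:
    name: str
    cv_percent: tuple[float, float]
    kept: bool


@dataclass
class ChannelQualityReport:
    """Per-channel coefficient-of-variation screen at a percent threshold."""

    threshold_percent: float
    channels: list[ChannelQuality] = field(default_factory=list)

    @property
    def kept_names(self) -> list[str]:
        return [c.name for c in self.channels if c.kept]

    @property
    def discarded_names(self) -> list[str]:
        return [c.name for c in self.channels if not c.kept]
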