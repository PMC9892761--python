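"""Raw-recording I/O, band-pass filtering, channel quality screening and the
modified Beer-Lambert conversion from optical density to hemoglobin
concentration changes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from xfnirs.types import (
    ChannelQuality,
    ChannelQualityReport,
    ExtinctionCoefficients,
    HemoRecording,
    MontageChannel,
    OpticalDensitySeries,
    RawRecording,
)

VALID_LABELS = frozenset({"left", "right", "rest"})


class FormatError(ValueError):
    """Raised for malformed input files."""


def expand_events(
    events: list[dict], n_samples: int, fs: float
) -> np.ndarray:
    """Expand an event schedule into a per-sample label stream.

    Samples not covered by any event are labeled "rest". Events are dicts
    with onset_s, duration_s and label keys.
    """
    labels = np.full(n_samples, "rest", dtype=object)
    for ev in events:
        label = ev["label"]
        if label not in VALID_LABELS:
            raise FormatError(f"unknown event label {label!r}")
        start = int(round(ev["onset_s"] * fs))
        stop = int(round((ev["onset_s"] + ev["duration_s"]) * fs))
        labels[max(start, 0) : min(stop, n_samples)] = label
    return labels


def read_recording(path: str | Path, format: str = "csv+json") -> RawRecording:
    """Read a raw recording from disk.

    The ``csv+json`` dialect expects ``<stem>.csv`` (columns
    ``time,<chan>_<l1>,<chan>_<l2>,...``), ``<stem>.montage.json`` and
    ``<stem>.events.json`` next to each other; ``path`` is the CSV.
    ``snirf`` reads a minimal continuous-wave SNIRF (HDF5) file.
    """
    path = Path(path)
    if format == "csv+json":
        return _read_csv_json(path)
    if format == "snirf":
        return _read_snirf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv_json(path: Path) -> RawRecording:
    if not path.exists():
        raise FileNotFoundError(path)
    stem = path.with_suffix("")
    montage_path = Path(str(stem) + ".montage.json")
    events_path = Path(str(stem) + ".events.json")
    if not montage_path.exists() or not events_path.exists():
        raise FormatError(
            f"missing montage/events sidecar for {path} "
            f"(expected {montage_path.name}, {events_path.name})"
        )

    with open(montage_path) as fh:
        mont_doc = json.load(fh)
    wavelengths = tuple(float(w) for w in mont_doc["wavelengths"])
    fs = float(mont_doc["sampling_rate_hz"])
    montage = [
        MontageChannel(
            name=c["name"],
            distance_mm=float(c.get("distance_mm", 30.0)),
            region=c.get("region"),
        )
        for c in mont_doc["channels"]
    ]

    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError("intensity CSV must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError("non-monotone timestamps in intensity CSV")

    n = len(df)
    intensity = np.empty((n, len(montage), 2))
    for ci, chan in enumerate(montage):
        for wi, wl in enumerate(wavelengths):
            col = f"{chan.name}_{wl:g}"
            if col not in df.columns:
                raise FormatError(f"missing channel column {col!r}")
            intensity[:, ci, wi] = df[col].to_numpy(dtype=float)

    with open(events_path) as fh:
        events = json.load(fh)
    labels = expand_events(events, n, fs)
    return RawRecording(
        sampling_rate_hz=fs,
        wavelengths=wavelengths,
        intensity=intensity,
        montage=montage,
        labels=labels,
    )


def _read_snirf(path: Path) -> RawRecording:
    import h5py

    def _scalar(ds):
        v = ds[()]
        if isinstance(v, bytes):
            return v.decode()
        return np.asarray(v).item() if np.ndim(v) == 0 else v

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"], dtype=float)
        t = np.asarray(data["time"], dtype=float)
        if t.size < 2:
            raise FormatError("SNIRF time vector too short to infer rate")
        fs = 1.0 / float(np.median(np.diff(t)))
        probe = nirs["probe"]
        wavelengths = tuple(np.asarray(probe["wavelength"], dtype=float)[:2])
        source_labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in np.asarray(probe["sourceLabels"]).ravel()
        ]
        detector_labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in np.asarray(probe["detectorLabels"]).ravel()
        ]
        # group measurement-list entries into (source, detector) channels
        ml_keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList") :]),
        )
        pairs: dict[tuple[int, int], dict[int, int]] = {}
        for col, key in enumerate(ml_keys):
            ml = data[key]
            s = int(_scalar(ml["sourceIndex"]))
            d = int(_scalar(ml["detectorIndex"]))
            w = int(_scalar(ml["wavelengthIndex"]))
            pairs.setdefault((s, d), {})[w] = col
        montage = []
        cols = []
        for (s, d), wl_map in sorted(pairs.items()):
            if set(wl_map) != {1, 2}:
                raise FormatError(
                    f"source {s}/detector {d}: need both wavelengths"
                )
            name = source_labels[s - 1] + detector_labels[d - 1]
            montage.append(MontageChannel(name=name))
            cols.append((wl_map[1], wl_map[2]))
        intensity = np.stack(
            [np.stack([series[:, a], series[:, b]], axis=1) for a, b in cols],
            axis=1,
        )
        events = []
        for key in nirs.keys():
            if key.startswith("stim"):
                stim = nirs[key]
                label = _scalar(stim["name"])
                if label not in VALID_LABELS:
                    continue
                onsets = np.atleast_2d(np.asarray(stim["data"], dtype=float))
                for row in onsets:
                    events.append(
                        {
                            "onset_s": float(row[0]),
                            "duration_s": float(row[1]),
                            "label": label,
                        }
                    )
    labels = expand_events(events, series.shape[0], fs)
    return RawRecording(
        sampling_rate_hz=fs,
        wavelengths=wavelengths,
        intensity=intensity,
        montage=montage,
        labels=labels,
    )


def apply_bandpass(
    rec: RawRecording, low_hz: float = 0.01, high_hz: float = 0.2, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass, applied per channel and wavelength.

    The default 0.01-0.2 Hz passband keeps the hemodynamic band while
    suppressing cardiac/respiratory oscillations and slow drift.
    """
    nyquist = rec.sampling_rate_hz / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist rate {nyquist}"
        )
    sos = butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate_hz, output="sos"
    )
    filtered = sosfiltfilt(sos, rec.intensity, axis=0)
    return RawRecording(
        sampling_rate_hz=rec.sampling_rate_hz,
        wavelengths=rec.wavelengths,
        intensity=filtered,
        montage=list(rec.montage),
        labels=rec.labels.copy(),
    )


def channel_quality_filter(
    rec: RawRecording, threshold: float = 7.5
) -> tuple[RawRecording, ChannelQualityReport]:
    """Discard channels whose intensity CV exceeds ``threshold`` percent.

    CV is std/mean * 100, computed per wavelength on the raw intensity; a
    channel is kept only if every wavelength passes. Zero-mean channels get
    CV = +inf and are discarded.
    """
    report = ChannelQualityReport(threshold_percent=threshold)
    keep_idx = []
    for ci, chan in enumerate(rec.montage):
        cvs = []
        for wi in range(2):
            x = rec.intensity[:, ci, wi]
            mean = x.mean()
            cvs.append(np.inf if mean == 0 else abs(x.std() / mean) * 100.0)
        kept = all(cv <= threshold for cv in cvs)
        report.channels.append(
            ChannelQuality(name=chan.name, cv_percent=(cvs[0], cvs[1]), kept=kept)
        )
        if kept:
            keep_idx.append(ci)
    out = RawRecording(
        sampling_rate_hz=rec.sampling_rate_hz,
        wavelengths=rec.wavelengths,
        intensity=rec.intensity[:, keep_idx, :],
        montage=[rec.montage[i] for i in keep_idx],
        labels=rec.labels.copy(),
    )
    return out, report


def intensity_to_od(
    rec: RawRecording, baseline: str | tuple[int, int] = "mean"
) -> OpticalDensitySeries:
    """Convert intensity to optical-density change dA = -log10(I / I0).

    ``baseline`` is either "mean" (I0 = mean over the whole recording) or an
    explicit (start, stop) sample range averaged per channel/wavelength.
    """
    I = rec.intensity
    bad = np.argwhere(I <= 0)
    if bad.size:
        t, c, w = bad[0]
        raise ValueError(
            f"nonpositive intensity at sample {t}, channel "
            f"{rec.montage[c].name!r}, wavelength {rec.wavelengths[w]:g} nm"
        )
    if baseline == "mean":
        I0 = I.mean(axis=0)
        spec = "mean over recording"
    else:
        start, stop = baseline
        if not (0 <= start < stop <= I.shape[0]):
            raise ValueError(f"invalid baseline range {baseline}")
        I0 = I[start:stop].mean(axis=0)
        spec = f"mean over samples [{start}, {stop})"
    if np.any(I0 <= 0):
        raise ValueError("baseline intensity must be strictly positive")
    delta_A = -np.log10(I / I0[None, :, :])
    return OpticalDensitySeries(
        delta_A=delta_A,
        wavelengths=rec.wavelengths,
        sampling_rate_hz=rec.sampling_rate_hz,
        montage=list(rec.montage),
        labels=rec.labels.copy(),
        baseline_spec=spec,
    )


def mbll_convert(
    od: OpticalDensitySeries,
    coeffs: ExtinctionCoefficients | None = None,
    montage: list[MontageChannel] | None = None,
) -> HemoRecording:
    """Modified Beer-Lambert law: per channel and sample,

        [dHbO; dHbR] = u / (l * d) * E^-1 [dA(l1); dA(l2)]

    with E the 2x2 extinction matrix (mM^-1 mm^-1), l the source-detector
    distance (mm), d the differential pathlength factor, and u the
    coefficient set's ``unit_scale`` (1000 reports uM).
    """
    if coeffs is None:
        coeffs = ExtinctionCoefficients(wavelengths=od.wavelengths)
    if montage is None:
        montage = od.montage
    det = np.linalg.det(coeffs.matrix)
    if abs(det) < 1e-15 or not np.isfinite(np.linalg.cond(coeffs.matrix)):
        raise ValueError("extinction coefficient matrix is singular")
    inv = np.linalg.inv(coeffs.matrix)
    n_t, n_c, _ = od.delta_A.shape
    delta_HbO = np.empty((n_t, n_c))
    delta_HbR = np.empty((n_t, n_c))
    for ci, chan in enumerate(montage):
        scale = coeffs.unit_scale / (chan.distance_mm * coeffs.dpf)
        conc = scale * (od.delta_A[:, ci, :] @ inv.T)
        delta_HbO[:, ci] = conc[:, 0]
        delta_HbR[:, ci] = conc[:, 1]
    return HemoRecording(
        delta_HbO=delta_HbO,
        delta_HbR=delta_HbR,
        sampling_rate_hz=od.sampling_rate_hz,
        montage=list(montage),
        labels=od.labels.copy(),
    )


def preprocess(
    rec: RawRecording,
    low_hz: float = 0.01,
    high_hz: float = 0.2,
    cv_threshold: float = 7.5,
    baseline: str | tuple[int, int] = "mean",
    coeffs: ExtinctionCoefficients | None = None,
) -> tuple[HemoRecording, ChannelQualityReport]:
    """Full preprocessing chain: CV screen -> band-pass -> OD -> MBLL."""
    kept, report = channel_quality_filter(rec, threshold=cv_threshold)
    od = intensity_to_od(kept, baseline=baseline)
    filtered = _bandpass_od(od, low_hz, high_hz)
    hemo = mbll_convert(filtered, coeffs=coeffs)
    return hemo, report


def _bandpass_od(
    od: OpticalDensitySeries, low_hz: float, high_hz: float, order: int = 4
) -> OpticalDensitySeries:
    # same zero-phase filter as apply_bandpass, on the OD series; filtering
    # OD (rather than raw intensity) keeps the MBLL input zero-centered
    nyquist = od.sampling_rate_hz / 2.0
    if high_hz >= nyquist:
        raise ValueError("high_hz must be below Nyquist")
    sos = butter(
        order, [low_hz, high_hz], btype="bandpass", fs=od.sampling_rate_hz, output="sos"
    )
    return OpticalDensitySeries(
        delta_A=sosfiltfilt(sos, od.delta_A, axis=0),
        wavelengths=od.wavelengths,
        sampling_rate_hz=od.sampling_rate_hz,
        montage=list(od.montage),
        labels=od.labels.copy(),
        baseline_spec=od.baseline_spec + f"; bandpass {low_hz}-{high_hz} Hz",
    )


def export_hemo_csv(hemo: HemoRecording, path: str | Path) -> None:
    """Write ``time,<chan>_HbO,...,<chan>_HbR,...,label`` CSV."""
    t = np.arange(hemo.n_samples) / hemo.sampling_rate_hz
    data = {"time": t}
    for ci, chan in enumerate(hemo.montage):
        data[f"{chan.name}_HbO"] = hemo.delta_HbO[:, ci]
    for ci, chan in enumerate(hemo.montage):
        data[f"{chan.name}_HbR"] = hemo.delta_HbR[:, ci]
    data["label"] = hemo.labels
    pd.DataFrame(data).to_csv(path, index=False)
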