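"""File formats: SNIRF (HDF5) and long-format CSV recordings, ROI maps,
cohort tables, connectivity matrices, and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import RawIntensityRecording

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_recording_csv",
    "read_recording_csv",
    "read_recording",
    "write_roi_map",
    "read_roi_map",
    "write_connectivity_tsv",
    "write_manifest",
    "file_sha256",
]


def write_snirf(recording: RawIntensityRecording, path) -> Path:
    """Write a recording as a minimal SNIRF v1.0 (HDF5) file."""
    path = Path(path)
    n_meas, n_t = recording.intensities.shape
    wavelengths = sorted(set(recording.wavelength.tolist()))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=recording.intensities.T)
        data.create_dataset("time", data=np.arange(n_t) / recording.fs)
        for k in range(n_meas):
            ml = data.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=int(recording.source[k]))
            ml.create_dataset("detectorIndex", data=int(recording.detector[k]))
            ml.create_dataset(
                "wavelengthIndex",
                data=wavelengths.index(float(recording.wavelength[k])) + 1,
            )
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("SubjectAge", data=float(recording.subject_age))
        meta.create_dataset(
            "SourceDetectorDistance", data=float(recording.source_detector_distance_cm)
        )
    return path


def read_snirf(path) -> RawIntensityRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible)."""
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        ts = np.asarray(data["dataTimeSeries"]).T
        time = np.asarray(data["time"])
        if time.size < 2:
            raise ValueError(f"{path}: time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = np.asarray(f["nirs/probe/wavelengths"], dtype=float)
        n_meas = ts.shape[0]
        src, det, wl = [], [], []
        for k in range(n_meas):
            ml = data[f"measurementList{k + 1}"]
            src.append(int(ml["sourceIndex"][()]))
            det.append(int(ml["detectorIndex"][()]))
            wl.append(float(wavelengths[int(ml["wavelengthIndex"][()]) - 1]))
        meta = f["nirs"].get("metaDataTags")
        age = float(meta["SubjectAge"][()]) if meta and "SubjectAge" in meta else 10.0
        dist = (
            float(meta["SourceDetectorDistance"][()])
            if meta and "SourceDetectorDistance" in meta
            else 3.0
        )
    return RawIntensityRecording(
        intensities=ts,
        wavelength=np.asarray(wl),
        source=np.asarray(src),
        detector=np.asarray(det),
        fs=fs,
        subject_age=age,
        source_detector_distance_cm=dist,
    )


def write_recording_csv(recording: RawIntensityRecording, path) -> Path:
    """Long-format CSV: columns time, source, detector, wavelength, intensity."""
    path = Path(path)
    n_meas, n_t = recording.intensities.shape
    t = np.arange(n_t) / recording.fs
    frames = []
    for k in range(n_meas):
        frames.append(
            pd.DataFrame(
                {
                    "time": t,
                    "source": recording.source[k],
                    "detector": recording.detector[k],
                    "wavelength": recording.wavelength[k],
                    "intensity": recording.intensities[k],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_recording_csv(path, subject_age: float = 10.0) -> RawIntensityRecording:
    df = pd.read_csv(path)
    required = {"time", "source", "detector", "wavelength", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    times = np.sort(df["time"].unique())
    if times.size < 2:
        raise ValueError(f"{path}: need at least two time points")
    fs = 1.0 / float(np.median(np.diff(times)))
    rows, wls, srcs, dets = [], [], [], []
    grouped = df.groupby(["source", "detector", "wavelength"], sort=True)
    for (s, d, w), sub in grouped:
        sub = sub.sort_values("time")
        if len(sub) != times.size:
            raise ValueError(
                f"{path}: measurement ({s},{d},{w}) has {len(sub)} samples, "
                f"expected {times.size}"
            )
        rows.append(sub["intensity"].to_numpy())
        srcs.append(int(s))
        dets.append(int(d))
        wls.append(float(w))
    return RawIntensityRecording(
        intensities=np.vstack(rows),
        wavelength=np.asarray(wls),
        source=np.asarray(srcs),
        detector=np.asarray(dets),
        fs=fs,
        subject_age=subject_age,
    )


def read_recording(path, format: str | None = None) -> RawIntensityRecording:
    """Dispatch on ``format`` or file extension ('snirf' or 'csv')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("snirf" if path.suffix == ".snirf" else "csv")
    if fmt == "snirf":
        return read_snirf(path)
    if fmt == "csv":
        return read_recording_csv(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_roi_map(roi_map: pd.DataFrame, path) -> Path:
    path = Path(path)
    roi_map.to_csv(path, index=False)
    return path


def read_roi_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"source", "detector", "roi", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: roi map missing columns {sorted(missing)}")
    return df


def write_connectivity_tsv(matrix: np.ndarray, roi_labels, path) -> Path:
    """Band/time-averaged connectivity as (source, target, value) rows."""
    path = Path(path)
    rows = []
    for ti, tgt in enumerate(roi_labels):
        for si, src in enumerate(roi_labels):
            if si == ti:
                continue
            rows.append({"source": src, "target": tgt, "value": matrix[ti, si]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, stage: str, parameters: dict, inputs: dict | None = None) -> Path:
    """JSON sidecar recording stage parameters, seeds, and input hashes."""
    from . import __version__

    path = Path(path)
    manifest = {
        "stage": stage,
        "package": "nirsconn",
        "version": __version__,
        "parameters": parameters,
        "inputs": {
            name: file_sha256(p) for name, p in (inputs or {}).items() if Path(p).exists()
        },
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
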