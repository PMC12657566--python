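"""SNIRF (HDF5) and plain-text I/O.

Recordings travel as SNIRF v1 files: ``/nirs/data1/dataTimeSeries``
holds the time x measurement matrix (channel-major, wavelength-minor
columns), ``measurementList`` groups carry the source/detector/
wavelength indices, the probe group the optode geometry (cm), and stim
groups the artifact annotations.  Channel roles (long/short) are not
stored; they are re-derived from separations on read.

Connectivity matrices are square CSV with channel-name headers; degree
tables and comparison reports are plain headered CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError
from .montage import Montage
from .recording import OpticalRecording

SNIRF_VERSION = "1.0"


def write_snirf(path: str | Path, rec: OpticalRecording) -> None:
    """Write an optical recording as a SNIRF v1 HDF5 file."""
    T, C, W = rec.intensities.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=SNIRF_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("nirsconnStage", data=rec.stage)

        data = nirs.create_group("data1")
        flat = rec.intensities.reshape(T, C * W)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times)
        k = 0
        for c in range(C):
            s, d = rec.montage.channels[c]
            for w in range(W):
                k += 1
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        probe.create_dataset("sourcePos3D", data=rec.montage.source_positions)
        probe.create_dataset("detectorPos3D", data=rec.montage.detector_positions)

        by_label: dict[str, list[list[float]]] = {}
        for onset, duration, label in rec.annotations:
            by_label.setdefault(label, []).append([onset, duration, 1.0])
        for i, (label, events) in enumerate(sorted(by_label.items()), start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=label)
            stim.create_dataset("data", data=np.asarray(events))


def _require(h5: h5py.Group, key: str):
    if key not in h5:
        raise FormatError(f"SNIRF file misses {h5.name}/{key}")
    return h5[key]


def _scalar(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path: str | Path) -> OpticalRecording:
    """Read a SNIRF v1 file into an :class:`OpticalRecording`.

    Channel roles are derived from source-detector separations via the
    montage's short-channel cut.  Raises :class:`FormatError` naming
    the absent group when the structure is malformed.
    """
    with h5py.File(path, "r") as f:
        _require(f, "formatVersion")
        nirs = _require(f, "nirs")
        data = _require(nirs, "data1")
        flat = np.asarray(_require(data, "dataTimeSeries"))
        time = np.asarray(_require(data, "time"))
        probe = _require(nirs, "probe")
        wavelengths = tuple(np.asarray(_require(probe, "wavelengths")).tolist())
        src = np.asarray(_require(probe, "sourcePos3D"))
        det = np.asarray(_require(probe, "detectorPos3D"))

        n_meas = flat.shape[1]
        meas = []
        for k in range(1, n_meas + 1):
            ml = _require(data, f"measurementList{k}")
            meas.append(
                (
                    int(np.asarray(_require(ml, "sourceIndex"))) - 1,
                    int(np.asarray(_require(ml, "detectorIndex"))) - 1,
                    int(np.asarray(_require(ml, "wavelengthIndex"))) - 1,
                )
            )
        channels: list[tuple[int, int]] = []
        col_of: dict[tuple[int, int, int], int] = {}
        for col, (s, d, w) in enumerate(meas):
            if (s, d) not in channels:
                channels.append((s, d))
            col_of[(s, d, w)] = col
        C, W = len(channels), len(wavelengths)
        if n_meas != C * W:
            raise FormatError(
                f"{n_meas} measurements inconsistent with {C} channels x {W} wavelengths"
            )
        cube = np.empty((flat.shape[0], C, W))
        for c, (s, d) in enumerate(channels):
            for w in range(W):
                cube[:, c, w] = flat[:, col_of[(s, d, w)]]

        if time.size < 2:
            raise FormatError("time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))

        annotations = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[key]
            label = _scalar(_require(stim, "name"))
            for onset, duration, _amp in np.atleast_2d(np.asarray(_require(stim, "data"))):
                annotations.append((float(onset), float(duration), label))

        stage = "intensity"
        if "metaDataTags" in nirs and "nirsconnStage" in nirs["metaDataTags"]:
            stage = _scalar(nirs["metaDataTags"]["nirsconnStage"])

    montage = Montage(src, det, channels)
    return OpticalRecording(
        intensities=cube,
        sampling_rate=fs,
        montage=montage,
        wavelengths=wavelengths,
        annotations=annotations,
        stage=stage,
    )


# --------------------------------------------------------------------------
# plain-text formats
# --------------------------------------------------------------------------

def read_annotations_tsv(path: str | Path) -> list[tuple[float, float, str]]:
    """Read a 3-column TSV (onset s, duration s, label)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["onset", "duration", "label"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"annotation TSV must have columns {expected}")
    return [
        (float(r.onset), float(r.duration), str(r.label)) for r in df.itertuples()
    ]


def write_annotations_tsv(path: str | Path, annotations) -> None:
    pd.DataFrame(annotations, columns=["onset", "duration", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_csv(path: str | Path, matrix: np.ndarray, names: list[str]) -> None:
    """Square matrix as CSV with channel-name header and index."""
    pd.DataFrame(matrix, index=names, columns=names).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.columns)
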