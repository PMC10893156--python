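"""Reading and writing recordings and matrix signals.

Supported containers:

* HDF5 — lossless; the native format for both recordings and matrix signals.
* CSV — one row per sample, a mandatory header naming channel columns plus
  ``label`` and ``repetition`` columns; comma-separated, '.' decimal.
* MATLAB Level-5 MAT — read-only, for NinaPro-style releases whose keys are
  ``emg``, ``stimulus`` (or ``restimulus``) and ``repetition``; key names are
  configurable per layout because database releases differ.

Conventions everywhere: time is axis 0, channels axis 1, class ids are
0-based with 0 = rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat

from .matrix import MatrixSignal
from .synthetic import Recording

__all__ = [
    "DatasetLayout", "LAYOUTS", "FormatError", "LayoutError",
    "load_recording", "save_recording",
    "save_matrix_signals", "load_matrix_signals",
]


class FormatError(ValueError):
    """The file does not contain the expected keys/columns."""


class LayoutError(ValueError):
    """The file's content contradicts the declared dataset layout."""


@dataclass(frozen=True)
class DatasetLayout:
    """Container key names and expected geometry for one database family."""

    name: str
    signal_key: str = "emg"
    label_key: str = "stimulus"
    repetition_key: str = "repetition"
    n_channels_expected: int | None = None
    fs_expected: float | None = None
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.grid_shape is not None and self.n_channels_expected is not None:
            r, c = self.grid_shape
            if r * c != self.n_channels_expected:
                raise ValueError("grid_shape must multiply to n_channels_expected")


LAYOUTS: dict[str, DatasetLayout] = {
    "ninapro_db1": DatasetLayout("ninapro_db1", "emg", "stimulus", "repetition",
                                 n_channels_expected=10, fs_expected=100.0,
                                 grid_shape=(2, 5)),
    "capgmyo": DatasetLayout("capgmyo", "emg", "stimulus", "repetition",
                             n_channels_expected=128, fs_expected=1000.0,
                             grid_shape=(8, 16)),
    "generic": DatasetLayout("generic"),
}


def _check_layout(samples: np.ndarray, fs: float, layout: DatasetLayout) -> None:
    if layout.n_channels_expected is not None and \
            samples.shape[1] != layout.n_channels_expected:
        raise LayoutError(
            f"layout {layout.name!r} expects {layout.n_channels_expected} channels, "
            f"file has {samples.shape[1]}")
    if layout.fs_expected is not None and fs is not None and \
            not np.isclose(fs, layout.fs_expected):
        raise LayoutError(
            f"layout {layout.name!r} expects fs={layout.fs_expected}, file has {fs}")


def load_recording(path, layout: DatasetLayout | str = "generic",
                   fs: float | None = None, subject_id: str | None = None
                   ) -> Recording:
    """Load a Recording from HDF5, CSV or MAT, validated against the layout.

    ``fs`` overrides/provides the sampling rate for containers that do not
    store one (CSV, MAT).
    """
    if isinstance(layout, str):
        layout = LAYOUTS[layout]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        rec = _load_hdf5(path, layout)
    elif suffix == ".csv":
        rec = _load_csv(path, fs)
    elif suffix == ".mat":
        rec = _load_mat(path, layout, fs)
    else:
        raise FormatError(f"unsupported container {suffix!r}")
    if fs is not None:
        rec.fs = float(fs)
    if subject_id is not None:
        rec.subject_id = subject_id
    _check_layout(rec.samples, rec.fs, layout)
    return rec


def _load_hdf5(path, layout):
    with h5py.File(path, "r") as f:
        for key in (layout.signal_key, layout.label_key, layout.repetition_key):
            if key not in f:
                raise FormatError(f"missing key {key!r} in {path}")
        return Recording(
            samples=f[layout.signal_key][()],
            fs=float(f.attrs.get("fs", 0.0)) or 1.0,
            labels=f[layout.label_key][()].astype(np.int64),
            repetition=f[layout.repetition_key][()].astype(np.int64),
            subject_id=str(f.attrs.get("subject_id", "")),
        )


def _load_csv(path, fs):
    df = pd.read_csv(path)
    for col in ("label", "repetition"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    if not chan_cols:
        raise FormatError(f"no channel columns (ch*) in {path}")
    return Recording(samples=df[chan_cols].to_numpy(dtype=np.float64),
                     fs=float(fs) if fs else 1.0,
                     labels=df["label"].to_numpy(dtype=np.int64),
                     repetition=df["repetition"].to_numpy(dtype=np.int64),
                     subject_id="")


def _load_mat(path, layout, fs):
    mat = loadmat(path)
    if layout.signal_key not in mat:
        raise FormatError(f"missing key {layout.signal_key!r} in {path}")
    label_key = layout.label_key
    if label_key not in mat:
        # NinaPro releases carry either 'stimulus' or re-labeled 'restimulus'
        alt = "restimulus" if label_key == "stimulus" else "stimulus"
        if alt in mat:
            label_key = alt
        else:
            raise FormatError(f"missing key {layout.label_key!r} in {path}")
    rep_key = layout.repetition_key
    if rep_key not in mat:
        if "rerepetition" in mat:
            rep_key = "rerepetition"
        else:
            raise FormatError(f"missing key {layout.repetition_key!r} in {path}")
    return Recording(samples=np.asarray(mat[layout.signal_key], dtype=np.float64),
                     fs=float(fs) if fs else (layout.fs_expected or 1.0),
                     labels=np.asarray(mat[label_key]).reshape(-1).astype(np.int64),
                     repetition=np.asarray(mat[rep_key]).reshape(-1).astype(np.int64),
                     subject_id="")


def save_recording(recording: Recording, path, format: str | None = None) -> None:
    """Write a Recording as HDF5 (lossless) or CSV."""
    if recording.n_samples == 0:
        raise ValueError("refusing to save an empty recording")
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("emg", data=recording.samples)
            f.create_dataset("stimulus", data=recording.labels)
            f.create_dataset("repetition", data=recording.repetition)
            f.attrs["fs"] = recording.fs
            f.attrs["subject_id"] = recording.subject_id
    elif format == "csv":
        cols = {f"ch{i}": recording.samples[:, i]
                for i in range(recording.n_channels)}
        cols["label"] = recording.labels
        cols["repetition"] = recording.repetition
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.15g")
    else:
        raise ValueError(f"unknown format {format!r}")


def save_matrix_signals(matrices: list[MatrixSignal], path) -> None:
    """Lossless HDF5 round trip of a matrix-signal batch, order preserved."""
    if not matrices:
        raise ValueError("nothing to save")
    grids = {m.source_grid for m in matrices}
    shapes = {m.pixels.shape for m in matrices}
    if len(grids) > 1 or len(shapes) > 1:
        raise ValueError(f"mixed grid/pixel sizes in one file: {grids}, {shapes}")
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=np.stack([m.pixels for m in matrices]))
        f.create_dataset("labels", data=np.array([m.label for m in matrices]))
        f.create_dataset("repetitions",
                         data=np.array([m.repetition for m in matrices]))
        f.create_dataset("index", data=np.arange(len(matrices)))
        sid = np.array([m.subject_id for m in matrices], dtype=h5py.string_dtype())
        f.create_dataset("subject_ids", data=sid)
        f.attrs["source_grid"] = matrices[0].source_grid


def load_matrix_signals(path) -> list[MatrixSignal]:
    with h5py.File(path, "r") as f:
        for key in ("pixels", "labels", "repetitions", "subject_ids", "index"):
            if key not in f:
                raise FormatError(f"missing key {key!r} in {path}")
        pixels = f["pixels"][()]
        labels = f["labels"][()]
        reps = f["repetitions"][()]
        sids = [s.decode() if isinstance(s, bytes) else str(s)
                for s in f["subject_ids"][()]]
        order = np.argsort(f["index"][()])
        grid = tuple(int(x) for x in f.attrs["source_grid"])
    return [MatrixSignal(pixels=pixels[i], label=int(labels[i]),
                         subject_id=sids[i], source_grid=grid,
                         repetition=int(reps[i]))
            for i in order]
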