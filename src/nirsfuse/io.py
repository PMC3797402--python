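"""Readers and writers for the external artifacts of the fusion pipeline.

Covers delimited fNIRS channel tables, BIDS-style event tables, NIfTI-1
volumes/masks, and 4-D NIfTI component/movie output, together with the
domain types they populate.  Conventions fixed here:

* fNIRS tables are channel-major (channels x samples), comma- or
  tab-delimited, first column = channel label, no header row.  Sampling
  rate and chromophore are sidecar metadata, not stored in the file.
* Events are 3-column TSV with header ``onset	duration	label``
  (seconds); onsets must be strictly increasing.
* Voxel flattening is C-order (last axis fastest) over the boolean mask,
  0-based indices; the default mask keeps finite & nonzero voxels and an
  explicit mask file always overrides it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """An input file violates the expected layout or contains bad values."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusParadigm:
    """A block-design stimulus: first onset, alternating task/rest blocks.

    The default construction ``StimulusParadigm(42.0, 21.0, 30.0, 10)``
    describes the right-finger-tapping protocol this package was built
    around: first trigger at 42 s, 21 s task alternating with 30 s rest,
    repeated 10 times, for a 552 s recording.
    """

    first_onset: float
    task_duration: float
    rest_duration: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.first_onset < 0:
            raise ValueError("first_onset must be >= 0")
        if self.task_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("task/rest durations must be > 0")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")

    @property
    def cycle_duration(self) -> float:
        return self.task_duration + self.rest_duration

    @property
    def total_duration(self) -> float:
        return self.first_onset + self.n_cycles * self.cycle_duration

    def onsets(self) -> np.ndarray:
        """Trigger onsets in seconds, one per cycle (0-based cycle k)."""
        k = np.arange(self.n_cycles, dtype=float)
        return self.first_onset + k * self.cycle_duration


@dataclass(frozen=True)
class EventTable:
    """Rows of (onset s, duration s, label); onsets strictly increasing."""

    frame: pd.DataFrame  # columns: onset, duration, label

    def __post_init__(self) -> None:
        required = ["onset", "duration", "label"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"event table missing column(s): {missing}")
        onsets = self.frame["onset"].to_numpy(dtype=float)
        durations = self.frame["duration"].to_numpy(dtype=float)
        if len(onsets) and onsets.min() < 0:
            raise FormatError("event onsets must be non-negative")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise FormatError("event onsets must be strictly increasing")
        if len(durations) and durations.min() < 0:
            raise FormatError("event durations must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset"].to_numpy(dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.frame["duration"].to_numpy(dtype=float)

    @property
    def labels(self) -> list[str]:
        return [str(x) for x in self.frame["label"]]


def paradigm_to_events(p: StimulusParadigm, label: str = "task") -> EventTable:
    """One event row per task block of the paradigm."""
    frame = pd.DataFrame(
        {
            "onset": p.onsets(),
            "duration": np.full(p.n_cycles, p.task_duration, dtype=float),
            "label": [label] * p.n_cycles,
        }
    )
    return EventTable(frame)


CHROMOPHORES = ("HbO2", "HbR", "OD")


@dataclass(frozen=True)
class FNIRSRecording:
    """Channel-major fNIRS time series.

    ``data`` is channels x samples; concentration change in μM for
    chromophore HbO2/HbR, or optical density (unitless) when
    ``chromophore == "OD"``.  ``wavelengths`` is metadata (nm) and is
    required only for OD recordings destined for Beer–Lambert conversion.
    """

    data: np.ndarray
    sampling_rate: float
    chromophore: str
    channel_labels: tuple[str, ...]
    wavelengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(str(c) for c in self.channel_labels))
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError("data must be channels x samples with >=1 channel, >=2 samples")
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.chromophore not in CHROMOPHORES:
            raise ValueError(f"chromophore must be one of {CHROMOPHORES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, **changes) -> "FNIRSRecording":
        return dataclasses.replace(self, data=data, **changes)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid: shape, affine, and boolean in-brain mask.

    In-mask voxels are flattened in C-order (last axis fastest); this is
    the order of every V-length vector in the package.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask", mask)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be 3 positive integers")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if mask.shape != shape:
            raise ValueError("mask shape must equal grid shape")
        if int(mask.sum()) < 1:
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        """V — the number of in-mask voxels."""
        return int(self.mask.sum())

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3-D volume to its V in-mask values (C-order)."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(f"volume shape {volume.shape} != grid shape {self.shape}")
        return volume[self.mask]

    def insert(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter V values back into a full 3-D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected {self.n_voxels} values, got {values.shape}")
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out


# ---------------------------------------------------------------------------
# fNIRS tables
# ---------------------------------------------------------------------------

def read_fnirs_table(
    path: str | Path,
    sampling_rate: float,
    chromophore: str,
    wavelengths: tuple[float, ...] = (),
) -> FNIRSRecording:
    """Read a channel-major delimited table into an FNIRSRecording.

    The delimiter (comma or tab) is sniffed from the first line.  The
    first column carries the channel label; every remaining cell must be
    numeric.  Ragged rows and non-numeric cells are reported with their
    row/column position.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table ({exc})") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected a label column plus >=2 sample columns")
    labels = [str(x).strip() for x in frame.iloc[:, 0]]
    body = frame.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {r}, column {c + 1}: {body.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: ragged row {r} (missing value at column {c + 1})")
    # re-parse from the raw strings: correctly-rounded floats, lossless
    # round trip (pandas' fast to_numeric path may drop the last ulp)
    values = np.array(
        [[float(x) for x in row] for row in body.to_numpy()], dtype=float
    )
    return FNIRSRecording(
        data=values,
        sampling_rate=sampling_rate,
        chromophore=chromophore,
        channel_labels=tuple(labels),
        wavelengths=wavelengths,
    )


def write_fnirs_table(rec: FNIRSRecording, path: str | Path, sep: str = "\t") -> None:
    """Write a recording as a channel-major delimited table (inverse of read).

    Values are written with shortest-round-trip float repr, so read back
    bit-exactly.
    """
    with open(path, "w") as fh:
        for label, row in zip(rec.channel_labels, rec.data):
            fh.write(label + sep + sep.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> EventTable:
    """Read a 3-column TSV (onset/duration/label, seconds) into an EventTable.

    Rows must already be sorted by onset: out-of-order input is an error,
    never silently reordered.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration", "label") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return EventTable(frame[["onset", "duration", "label"]].copy())


def write_events(events: EventTable, path: str | Path) -> None:
    events.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(
    path: str | Path, mask_path: str | Path | None = None
) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3-D or 4-D NIfTI-1 volume and its grid.

    The mask comes from ``mask_path`` (nonzero = inside) when given;
    otherwise the default mask keeps voxels that are finite in every
    frame and nonzero in at least one.  An all-zero volume without an
    explicit mask is rejected ("empty default mask").
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises several types on bad headers
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3-D or 4-D data, got {data.ndim}-D")
    shape3 = data.shape[:3]
    if mask_path is not None:
        mimg = nib.load(str(Path(mask_path)))
        mask = np.asarray(mimg.get_fdata()) != 0
        if mask.shape != shape3:
            raise FormatError(
                f"mask shape {mask.shape} does not match volume shape {shape3}"
            )
    else:
        if data.ndim == 3:
            mask = np.isfinite(data) & (data != 0)
        else:
            mask = np.all(np.isfinite(data), axis=-1) & np.any(data != 0, axis=-1)
        if not mask.any():
            raise FormatError(f"{path}: empty default mask (volume is all zero)")
    grid = VolumeGrid(shape=shape3, affine=affine, mask=mask)
    return data, grid


def volume_to_maps(data: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Flatten a 3-D or 4-D array into an n x V matrix of in-mask values."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        return grid.extract(data)[None, :]
    if data.ndim == 4:
        return np.stack([grid.extract(data[..., k]) for k in range(data.shape[-1])])
    raise ValueError("expected a 3-D or 4-D array")


def write_maps(maps: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write an n x V matrix as a 4-D float32 NIfTI (one map per frame).

    Out-of-mask voxels are written as 0.  Round trip is lossless within
    float32.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[1] != grid.n_voxels:
        raise ValueError(
            f"maps have V={maps.shape[1]} but grid mask has {grid.n_voxels} voxels"
        )
    vol = np.zeros(grid.shape + (maps.shape[0],), dtype=np.float32)
    for k in range(maps.shape[0]):
        vol[..., k][grid.mask] = maps[k].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, grid.affine), str(path))


def write_component_maps(maps, grid: VolumeGrid, path: str | Path) -> None:
    """Write a component/section map set (object with ``.maps`` or an
    n x V array) as a 4-D NIfTI; errors if V mismatches the grid."""
    write_maps(getattr(maps, "maps", maps), grid, path)


def write_mask(grid: VolumeGrid, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine), str(path)
    )


def write_timecourses(
    time_axis: np.ndarray,
    columns: np.ndarray,
    path: str | Path,
    prefix: str = "comp",
) -> None:
    """Write T x k time courses as TSV; first column is time in seconds."""
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.shape[0] != len(time_axis):
        columns = columns.T
    if columns.shape[0] != len(time_axis):
        raise ValueError("time axis and columns disagree in length")
    frame = pd.DataFrame(
        columns, columns=[f"{prefix}{i + 1}" for i in range(columns.shape[1])]
    )
    frame.insert(0, "time_s", np.asarray(time_axis, dtype=float))
    frame.to_csv(path, sep="\t", index=False)


def read_timecourses(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_timecourses` -> (time_axis, T x k matrix)."""
    frame = pd.read_csv(path, sep="\t")
    if "time_s" not in frame.columns:
        raise FormatError(f"{path}: missing time_s column")
    t = frame.pop("time_s").to_numpy(dtype=float)
    return t, frame.to_numpy(dtype=float)
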