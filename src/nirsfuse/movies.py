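"""Spatiotemporal snapshot/movie reconstruction from joint components.

Two dual constructions over a chosen component subset (T = temporal
columns t_i, S = spatial columns s_i):

* fMRI movie  M_fmri  = |T_sub| · S_subᵀ — at each time point, the
  spatial maps weighted by the magnitude of their fNIRS time courses
  ("where", animated over time).
* fNIRS movie M_fnirs = T_sub · |S_sub|ᵀ — per voxel, the temporal
  components weighted by the magnitude of the voxel's spatial loading
  ("when", resolved per voxel); temporal signs are preserved.

The absolute value enters on the weighting modality because the pair is
fused through a single shared mixing parameter, so only the weighted
modality's sign is meaningful in each construction.  Display
thresholding (|Z| > z) is applied at export only; stored movie values
are unthresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .jica import JointComponents


@dataclass(frozen=True)
class MovieFrames:
    """T x V movie matrices for a component subset; either kind may be unset."""

    component_subset: tuple[int, ...]  # 1-based component numbers
    time_axis: np.ndarray
    fmri_movie: np.ndarray | None = None
    fnirs_movie: np.ndarray | None = None
    temporal_subset: np.ndarray | None = None  # T x k, for snapshot panels

    @property
    def n_frames(self) -> int:
        movie = self.fmri_movie if self.fmri_movie is not None else self.fnirs_movie
        return 0 if movie is None else movie.shape[0]


def _subset_indices(comps: JointComponents, subset: list[int]) -> list[int]:
    if not subset:
        raise ValueError("component subset must be non-empty")
    idx = []
    for c in subset:
        if not (1 <= c <= comps.n_components):
            raise IndexError(
                f"component number {c} out of range 1..{comps.n_components}"
            )
        idx.append(int(c) - 1)
    return idx


def compute_fmri_movie(comps: JointComponents, subset: list[int]) -> MovieFrames:
    """M_fmri = |T_sub| · S_subᵀ: frame at time t is Σ_i |t_i(t)|·s_iᵀ.

    ``subset`` uses 1-based component numbers as reported by the fit.
    """
    idx = _subset_indices(comps, subset)
    Tsub = comps.temporal[:, idx]
    Ssub = comps.spatial[:, idx]
    movie = np.abs(Tsub) @ Ssub.T
    return MovieFrames(
        component_subset=tuple(int(c) for c in subset),
        time_axis=_time_axis(comps),
        fmri_movie=movie,
        temporal_subset=Tsub,
    )


def compute_fnirs_movie(comps: JointComponents, subset: list[int]) -> MovieFrames:
    """M_fnirs = T_sub · |S_sub|ᵀ: voxel v's time course is Σ_i t_i·|s_i(v)|."""
    idx = _subset_indices(comps, subset)
    Tsub = comps.temporal[:, idx]
    Ssub = comps.spatial[:, idx]
    movie = Tsub @ np.abs(Ssub).T
    return MovieFrames(
        component_subset=tuple(int(c) for c in subset),
        time_axis=_time_axis(comps),
        fnirs_movie=movie,
        temporal_subset=Tsub,
    )


def compute_movies(comps: JointComponents, subset: list[int]) -> MovieFrames:
    """Both movie kinds in one MovieFrames."""
    a = compute_fmri_movie(comps, subset)
    b = compute_fnirs_movie(comps, subset)
    return MovieFrames(
        component_subset=a.component_subset,
        time_axis=a.time_axis,
        fmri_movie=a.fmri_movie,
        fnirs_movie=b.fnirs_movie,
        temporal_subset=a.temporal_subset,
    )


def _time_axis(comps: JointComponents) -> np.ndarray:
    if comps.time_axis is not None:
        return np.asarray(comps.time_axis, dtype=float)
    return np.arange(comps.temporal.shape[0], dtype=float)


class ThresholdedMap(NamedTuple):
    values: np.ndarray
    n_survivors: int


def threshold_display(map_values: np.ndarray, z_abs: float = 1.5) -> ThresholdedMap:
    """Zero out |z| <= z_abs for display; report surviving voxel count.

    The conventional display threshold for the z-scored component maps
    is |Z| > 1.5.
    """
    if z_abs < 0:
        raise ValueError("z_abs must be >= 0")
    v = np.asarray(map_values, dtype=float)
    out = np.where(np.abs(v) > z_abs, v, 0.0)
    n = int(np.count_nonzero(np.abs(v) > z_abs))
    if n == 0:
        warnings.warn("no voxel survives the display threshold", stacklevel=2)
    return ThresholdedMap(values=out, n_survivors=n)


class Snapshot(NamedTuple):
    frame: np.ndarray  # V-vector at the nearest sample
    temporal_values: np.ndarray  # the subset's temporal component values there
    sample_index: int
    time: float


def snapshot_at(movie: MovieFrames, t: float, kind: str = "fmri") -> Snapshot:
    """Nearest-sample frame at time t plus the subset's temporal values.

    This is the numeric content of a published "snapshot" panel: the
    weighted map on the left, the component time-course values at that
    instant on the right.
    """
    axis = np.asarray(movie.time_axis, dtype=float)
    if not (axis.min() <= t <= axis.max()):
        raise ValueError(
            f"t={t} s outside the movie time axis [{axis.min()}, {axis.max()}] s"
        )
    data = movie.fmri_movie if kind == "fmri" else movie.fnirs_movie
    if data is None:
        raise ValueError(f"movie has no {kind!r} frames")
    k = int(np.argmin(np.abs(axis - t)))
    temporal = (
        movie.temporal_subset[k]
        if movie.temporal_subset is not None
        else np.empty(0)
    )
    return Snapshot(frame=data[k], temporal_values=temporal, sample_index=k, time=float(axis[k]))
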