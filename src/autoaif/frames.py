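"""Frame schedules, dynamic-image I/O, brain masking and TAC-matrix construction.

A dynamic PET acquisition is described by a :class:`FrameSchedule` (contiguous
frame start/duration pairs, seconds).  The 4D image ``F(X, Y, Z, n)`` is held in
a :class:`DynamicImage`; the data-preparation step selects brain voxels
(:func:`brain_mask`) and rearranges their time courses into the voxel-by-frame
matrix ``F̂(M, n)`` (:func:`extract_tac_matrix`) that every downstream step
consumes.

Activity is expressed in kBq/mL throughout; all evaluation metrics are
unit-invariant ratios, so the unit is presentational.  Voxel coordinates are
0-based indices; the time axis uses frame midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "VoxelMask",
    "TACMatrix",
    "build_frame_schedule",
    "frame_midtimes",
    "brain_mask",
    "extract_tac_matrix",
    "scatter_tac_matrix",
    "load_schedule",
    "save_schedule",
    "load_dynamic_image",
    "save_dynamic_image",
    "PAPER_FRAME_SPEC",
]

#: Frame blocks (count, duration s) of the 65-min / 62-frame acquisition grid
#: used throughout: 2x10 s, 30x2 s, 4x10 s, 8x30 s, 4x60 s, 5x120 s, 9x300 s.
PAPER_FRAME_SPEC: tuple[tuple[int, float], ...] = (
    (2, 10.0),
    (30, 2.0),
    (4, 10.0),
    (8, 30.0),
    (4, 60.0),
    (5, 120.0),
    (9, 300.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start and duration times (seconds) of a dynamic acquisition.

    Frames must be contiguous and non-overlapping:
    ``start[i+1] == start[i] + duration[i]``.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.ndim != 1 or start.size != duration.size:
            raise ValueError("start and duration must be 1D vectors of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(duration <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + duration[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def total_span(self) -> float:
        """Acquisition end time in seconds (first frame starts at start[0])."""
        return float(self.end[-1])

    @property
    def midtimes(self) -> np.ndarray:
        return self.start + self.duration / 2.0


def build_frame_schedule(spec) -> FrameSchedule:
    """Expand a compact ``[(count, duration_s), ...]`` spec into a schedule.

    The first frame starts at t = 0 s.
    """
    spec = list(spec)
    if not spec:
        raise ValueError("frame spec must not be empty")
    durations = []
    for count, dur in spec:
        count = int(count)
        if count < 1:
            raise ValueError("frame counts must be >= 1")
        if not np.isfinite(dur) or dur <= 0:
            raise ValueError("frame durations must be positive")
        durations.extend([float(dur)] * count)
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(start=starts, duration=durations)


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times in seconds (strictly increasing)."""
    return schedule.midtimes


@dataclass
class DynamicImage:
    """A 4D dynamic PET volume: activity (kBq/mL) on an X*Y*Z*n grid.

    ``fwhm`` records the effective isotropic image resolution in mm (native
    scanner resolution combined with any reconstruction / simulation blur).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule
    fwhm: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("dynamic image must be 4D (X, Y, Z, frames)")
        if any(s < 1 for s in self.values.shape[:3]):
            raise ValueError("spatial dimensions must be >= 1")
        if self.values.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"4th dimension ({self.values.shape[3]}) must equal "
                f"schedule.n_frames ({self.schedule.n_frames})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        self.voxel_size = vs
        self.fwhm = float(self.fwhm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def time_average(self) -> np.ndarray:
        """Duration-weighted time-averaged 3D image."""
        w = self.schedule.duration / self.schedule.duration.sum()
        return np.tensordot(self.values, w, axes=([3], [0]))


@dataclass(frozen=True)
class VoxelMask:
    """A set of included voxel coordinates (0-based 3D indices).

    Coordinates are stored in canonical (lexicographic) order and must be
    unique and inside the image bounds they refer to.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.intp)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (K, 3) array of voxel indices")
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        coords = coords[order]
        if coords.shape[0] > 1 and np.any(np.all(np.diff(coords, axis=0) == 0, axis=1)):
            raise ValueError("duplicate voxel coordinates in mask")
        if coords.size and np.any(coords < 0):
            raise ValueError("voxel coordinates must be non-negative")
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_bool(cls, mask: np.ndarray) -> "VoxelMask":
        return cls(np.argwhere(np.asarray(mask, dtype=bool)))

    def to_bool(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        if self.coords.size:
            out[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = True
        return out

    def __len__(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class TACMatrix:
    """Voxel-by-frame activity matrix F̂(M, n) with voxel coordinates retained.

    Row order is deterministic: lexicographic by voxel coordinate.
    """

    activities: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        acts = np.asarray(self.activities)
        idx = np.asarray(self.voxel_index, dtype=np.intp)
        if acts.ndim != 2:
            raise ValueError("activities must be a 2D (voxels x frames) matrix")
        if idx.ndim != 2 or idx.shape != (acts.shape[0], 3):
            raise ValueError("voxel_index must be (M, 3) matching activities rows")
        object.__setattr__(self, "activities", acts)
        object.__setattr__(self, "voxel_index", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.activities.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.activities.shape[1])


def brain_mask(
    image: DynamicImage,
    axial_extent_mm: float = 200.0,
    threshold: float = 1.0,
) -> VoxelMask:
    """Select brain voxels by time-averaged activity and axial coverage.

    A voxel is included iff its duration-weighted time-mean activity is
    strictly greater than ``threshold`` (default 1 image unit) and its axial
    (z) coordinate lies within the top ``axial_extent_mm`` (default 20 cm, the
    head coverage of current clinical scanners) measured downward from the
    most superior supra-threshold slice.

    An image entirely below threshold yields an empty mask with a warning.
    """
    mean_img = image.time_average()
    above = mean_img > threshold
    if not above.any():
        warnings.warn("image entirely below threshold; empty brain mask", stacklevel=2)
        return VoxelMask(np.empty((0, 3), dtype=np.intp))
    vz = image.voxel_size[2]
    z_top = int(np.max(np.nonzero(above.any(axis=(0, 1)))[0]))
    z_min = z_top - int(np.floor(axial_extent_mm / vz))
    if z_min > 0:
        above[:, :, :z_min] = False
    return VoxelMask.from_bool(above)


def extract_tac_matrix(image: DynamicImage, mask: VoxelMask) -> TACMatrix:
    """Arrange the masked voxels' time courses into the 2D matrix F̂(M, n)."""
    if len(mask) == 0:
        raise ValueError("mask is empty; cannot extract TAC matrix")
    shape = image.shape
    if np.any(mask.coords >= np.asarray(shape)):
        raise ValueError("mask coordinates outside image bounds")
    c = mask.coords
    acts = image.values[c[:, 0], c[:, 1], c[:, 2], :]
    return TACMatrix(activities=acts, voxel_index=c)


def scatter_tac_matrix(tacs: TACMatrix, shape: tuple[int, int, int]) -> np.ndarray:
    """Scatter TAC rows back onto a zero 4D grid (inverse of extraction)."""
    out = np.zeros(tuple(shape) + (tacs.n_frames,), dtype=tacs.activities.dtype)
    c = tacs.voxel_index
    out[c[:, 0], c[:, 1], c[:, 2], :] = tacs.activities
    return out


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 for 4D images, two-column CSV for frame schedules.

def save_schedule(schedule: FrameSchedule, path) -> None:
    pd.DataFrame({"start_s": schedule.start, "duration_s": schedule.duration}).to_csv(
        path, index=False
    )


def load_schedule(path) -> FrameSchedule:
    """Read a schedule from CSV with ``start_s, duration_s`` columns.

    A headerless two-column file is also accepted.
    """
    df = pd.read_csv(path)
    if "start_s" in df.columns and "duration_s" in df.columns:
        return FrameSchedule(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))
    df = pd.read_csv(path, header=None)
    if df.shape[1] != 2:
        raise ValueError("schedule CSV must have columns start_s, duration_s")
    return FrameSchedule(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def save_dynamic_image(image: DynamicImage, path) -> None:
    affine = np.diag(list(image.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine)
    img.header.set_zooms(image.voxel_size + (1.0,))
    nib.save(img, str(path))


def load_dynamic_image(path, schedule: FrameSchedule, fwhm: float = 0.0) -> DynamicImage:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(dtype=np.float32))
    if values.ndim != 4:
        raise ValueError("expected a 4D NIfTI volume (4th dimension = frames)")
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(
        values=values,
        voxel_size=tuple(float(z) for z in zooms),
        schedule=schedule,
        fwhm=fwhm,
    )
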