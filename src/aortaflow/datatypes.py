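"""Shared data containers for the 4D flow analysis pipeline.

Array conventions
-----------------
* velocity: ``(T, X, Y, Z, 3)`` float64, m/s, components along the grid axes.
* magnitudes: ``(T, 4, X, Y, Z)`` float64, arbitrary units >= 0. Index 0 is the
  motion-compensated reference ``|S|``; indices 1..3 are the three encoded
  magnitudes ``|S_i|`` of a four-point asymmetric velocity encoding.
* Physical coordinates are millimetres, voxel-center convention:
  ``mm = 0-based index * voxel_spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_NAMES = ("AAo", "DAo", "SAA", "IAA")
WHOLE = "Whole"
ALL_REGIONS = (WHOLE,) + REGION_NAMES


def _as_vec3(x) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.shape != (3,):
        raise ValueError(f"expected scalar or length-3 vector, got shape {a.shape}")
    return a


@dataclass
class FlowDataset:
    """Time-resolved velocity vector field plus motion-encoding magnitudes."""

    velocity: np.ndarray
    magnitudes: np.ndarray
    venc: np.ndarray
    voxel_spacing: np.ndarray
    timeframe_fractions: np.ndarray
    superior_axis: int = 2
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.venc = _as_vec3(self.venc)
        self.voxel_spacing = _as_vec3(self.voxel_spacing)
        self.timeframe_fractions = np.asarray(self.timeframe_fractions, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (T, X, Y, Z, 3)")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite values")
        if self.magnitudes.ndim != 5 or self.magnitudes.shape[1] != 4:
            raise ValueError("magnitudes must have shape (T, 4, X, Y, Z)")
        if self.magnitudes.shape[0] != self.velocity.shape[0]:
            raise ValueError("velocity and magnitudes disagree on timeframe count")
        if self.magnitudes.shape[2:] != self.velocity.shape[1:4]:
            raise ValueError("velocity and magnitudes disagree on grid shape")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.timeframe_fractions.shape != (self.velocity.shape[0],):
            raise ValueError("timeframe_fractions must have one entry per timeframe")
        if self.velocity.shape[0] > 1 and np.any(np.diff(self.timeframe_fractions) <= 0):
            raise ValueError("timeframe_fractions must be strictly increasing")
        if np.any((self.timeframe_fractions < 0) | (self.timeframe_fractions >= 1)):
            raise ValueError("timeframe_fractions must lie in [0, 1)")
        if np.any(self.venc <= 0):
            raise ValueError("venc must be positive")

    @property
    def n_timeframes(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.velocity.shape[1:4])

    def speed(self) -> np.ndarray:
        """Voxel speed |v|, shape (T, X, Y, Z)."""
        return np.linalg.norm(self.velocity, axis=-1)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "FlowDataset":
        return FlowDataset(
            velocity=self.velocity.copy(),
            magnitudes=self.magnitudes.copy(),
            venc=self.venc.copy(),
            voxel_spacing=self.voxel_spacing.copy(),
            timeframe_fractions=self.timeframe_fractions.copy(),
            superior_axis=self.superior_axis,
            provenance=list(self.provenance),
        )


@dataclass
class StaticTissueMask:
    """Voxels considered motion-free, used for background phase-offset fitting."""

    mask: np.ndarray
    temporal_std: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.temporal_std = np.asarray(self.temporal_std, dtype=float)
        if self.mask.shape != self.temporal_std.shape:
            raise ValueError("mask and temporal_std shapes differ")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationMask:
    """Binary lumen mask on the acquisition grid."""

    mask: np.ndarray
    voxel_spacing: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_spacing = _as_vec3(self.voxel_spacing)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("segmentation mask is empty")

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.voxel_spacing))


@dataclass
class Centerline:
    """Ordered lumen centerline with cumulative arc length, both in mm."""

    points: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.s.shape != (self.points.shape[0],):
            raise ValueError("s must have one value per point")
        if self.points.shape[0] < 2:
            raise ValueError("centerline needs at least two points")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the 3D position at arc length ``s``."""
        s = float(np.clip(s, self.s[0], self.s[-1]))
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, self.s, self.points[:, k])
        return out

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Centerline":
        points = np.asarray(points, dtype=float)
        steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
        keep = np.concatenate([[True], steps > 0])
        points = points[keep]
        steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(steps)])
        return cls(points=points, s=s)


@dataclass
class LandmarkSet:
    """Arc-length positions (mm) of the anatomical landmarks on a centerline."""

    aortic_valve: float
    arch_top: float
    left_subclavian: float
    renal_branches: float
    iliac_bifurcation: float

    def __post_init__(self) -> None:
        order = [
            self.aortic_valve,
            self.arch_top,
            self.left_subclavian,
            self.renal_branches,
            self.iliac_bifurcation,
        ]
        if any(b <= a for a, b in zip(order, order[1:])):
            names = [
                "aortic_valve",
                "arch_top",
                "left_subclavian",
                "renal_branches",
                "iliac_bifurcation",
            ]
            bad = [
                f"{names[i]}={order[i]:.2f} !< {names[i + 1]}={order[i + 1]:.2f}"
                for i in range(4)
                if order[i + 1] <= order[i]
            ]
            raise ValueError("landmark ordering violated: " + "; ".join(bad))


@dataclass
class RegionPartition:
    """Four-region division of the aorta along centerline arc length.

    ``intervals`` maps region name -> (s_start, s_end); the intervals tile
    [valve, iliac). ``labels`` assigns each lumen voxel the integer code of its
    nearest centerline point's region (0 = outside lumen, 1..4 = AAo..IAA).
    """

    intervals: dict[str, tuple[float, float]]
    labels: np.ndarray | None = None

    REGION_CODES = {name: i + 1 for i, name in enumerate(REGION_NAMES)}

    def region_of_s(self, s: float) -> str:
        last = REGION_NAMES[-1]
        for name in REGION_NAMES:
            lo, hi = self.intervals[name]
            if lo <= s < hi or (name == last and s == hi):
                return name
        raise ValueError(f"arc length {s} outside partition range")

    def region_voxels(self, region: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("partition carries no voxel labels")
        if region == WHOLE:
            return self.labels > 0
        return self.labels == self.REGION_CODES[region]


@dataclass
class RegionGeometry:
    """Geometric descriptors of one aortic region."""

    region: str
    tortuosity: float
    length: float
    chord: float
    diameter: float
    volume: float

    def __post_init__(self) -> None:
        if self.length < self.chord - 1e-9:
            raise ValueError("centerline length cannot be below the chord")
        if self.tortuosity < -1e-9:
            raise ValueError("tortuosity must be non-negative")
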