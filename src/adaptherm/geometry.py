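"""Rotated slice-frame geometry around the applicator axis.

All acquisition planes share one line in space — the main axis of the
ablation applicator — and are rotated uniformly around it.  A frame is a 2D
pixel grid whose *rows* run parallel to that axis and whose *columns* run
radially in the plane; the column ``axis_column`` coincides with the axis for
every rotation angle.  World coordinates are millimetres; the axis is aligned
with the z dimension of the reconstruction volume and passes through the
volume centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "SliceFrame",
    "VolumeGrid",
    "build_slice_frames",
    "slice_to_world",
    "world_to_slice",
    "sample_volume",
    "orthogonal_distance",
]


@dataclass(frozen=True)
class SliceFrame:
    """One rotated acquisition plane.

    Parameters
    ----------
    angle : float
        In-plane rotation about the applicator axis, degrees in [0, 180).
    matrix : tuple of int
        (rows, cols) of the pixel grid; rows run along the axis direction.
    pixel_spacing : float
        In-plane pixel size in mm (isotropic).
    slice_thickness : float
        Through-plane thickness in mm (thin-plane sampling is assumed).
    axis_column : float
        Column index that lies on the applicator axis.
    axis_origin : tuple of float
        World point (mm) on the axis that row ``(rows - 1) / 2`` maps to.
    axis_direction : tuple of float
        Unit vector of the axis in world coordinates (the z axis by default).
    """

    angle: float
    matrix: tuple[int, int] = (256, 256)
    pixel_spacing: float = 1.0
    slice_thickness: float = 5.0
    axis_column: float | None = None
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.axis_column is None:
            object.__setattr__(self, "axis_column", (self.matrix[1] - 1) / 2.0)
        d = np.asarray(self.axis_direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_direction must be non-zero")
        object.__setattr__(self, "axis_direction", tuple(d / n))

    @property
    def radial_direction(self) -> np.ndarray:
        """In-plane unit vector perpendicular to the axis for this angle."""
        a = np.deg2rad(self.angle)
        return np.array([np.cos(a), np.sin(a), 0.0])

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SliceFrame":
        d = json.loads(s)
        d["matrix"] = tuple(d["matrix"])
        d["axis_origin"] = tuple(d["axis_origin"])
        d["axis_direction"] = tuple(d["axis_direction"])
        return cls(**d)


@dataclass
class VolumeGrid:
    """Axis-aligned reconstruction grid (voxel-centre convention).

    The applicator axis runs along z through the in-plane centre of the grid.
    """

    shape: tuple[int, int, int] = (60, 60, 60)
    spacing: float = 1.0
    origin: tuple[float, float, float] | None = None
    field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.origin is None:
            # centre the grid on the world origin so the axis (z line through
            # x=y=0) passes through the in-plane centre
            self.origin = tuple(-(n - 1) / 2.0 * self.spacing for n in self.shape)
        if self.field is None:
            self.field = np.zeros(self.shape, dtype=np.float64)
        else:
            self.field = np.asarray(self.field, dtype=np.float64)
            if self.field.shape != tuple(self.shape):
                raise ValueError("field shape does not match grid shape")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.shape[i])
            for i in range(3)
        )

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.shape, self.spacing, self.origin, self.field.copy())

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (mm)."""
        p = np.atleast_2d(np.asarray(points, float))
        return (p - np.asarray(self.origin)) / self.spacing


def build_slice_frames(
    n_orientations: int,
    matrix: tuple[int, int] = (256, 256),
    pixel_spacing: float = 1.0,
    slice_thickness: float = 5.0,
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[SliceFrame]:
    """Uniformly distributed frames: angles ``k * 180 / n``, k = 0..n-1."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    step = 180.0 / n_orientations
    return [
        SliceFrame(
            angle=k * step,
            matrix=tuple(matrix),
            pixel_spacing=pixel_spacing,
            slice_thickness=slice_thickness,
            axis_origin=axis_origin,
        )
        for k in range(n_orientations)
    ]


def _check_pixel(frame: SliceFrame, pixel) -> tuple[np.ndarray, np.ndarray]:
    px = np.atleast_2d(np.asarray(pixel, float))
    rows, cols = px[:, 0], px[:, 1]
    nr, nc = frame.matrix
    if np.any((rows < 0) | (rows > nr - 1) | (cols < 0) | (cols > nc - 1)):
        raise ValueError("pixel outside matrix bounds")
    return rows, cols


def slice_to_world(frame: SliceFrame, pixel) -> np.ndarray:
    """World coordinates (mm) of a (row, col) pixel on a rotated frame.

    Pixels on ``axis_column`` land on the axis line for every angle.
    Accepts a single pixel or an (n, 2) array; returns (3,) or (n, 3).
    """
    single = np.asarray(pixel).ndim == 1
    rows, cols = _check_pixel(frame, pixel)
    nr, _ = frame.matrix
    z = (rows - (nr - 1) / 2.0) * frame.pixel_spacing
    u = (cols - frame.axis_column) * frame.pixel_spacing
    origin = np.asarray(frame.axis_origin)
    axis = np.asarray(frame.axis_direction)
    radial = frame.radial_direction
    pts = origin + np.outer(z, axis) + np.outer(u, radial)
    return pts[0] if single else pts


def world_to_slice(frame: SliceFrame, point) -> np.ndarray:
    """Inverse of :func:`slice_to_world` for points lying in the frame plane."""
    single = np.asarray(point).ndim == 1
    p = np.atleast_2d(np.asarray(point, float)) - np.asarray(frame.axis_origin)
    z = p @ np.asarray(frame.axis_direction)
    u = p @ frame.radial_direction
    nr, _ = frame.matrix
    rows = z / frame.pixel_spacing + (nr - 1) / 2.0
    cols = u / frame.pixel_spacing + frame.axis_column
    out = np.stack([rows, cols], axis=1)
    return out[0] if single else out


def sample_volume(
    volume: VolumeGrid,
    points,
    boundary_value: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of the volume's scalar field at world points.

    Exact at voxel centres.  Points outside the volume receive
    ``boundary_value`` (default: the mean of the six boundary faces) and are
    flagged in the returned boolean array.

    Returns
    -------
    values : ndarray
        Interpolated temperatures, same leading shape as ``points``.
    outside : ndarray of bool
        True where the point fell outside the grid.
    """
    single = np.asarray(points).ndim == 1
    pts = np.atleast_2d(np.asarray(points, float))
    if boundary_value is None:
        f = volume.field
        faces = [f[0], f[-1], f[:, 0], f[:, -1], f[:, :, 0], f[:, :, -1]]
        boundary_value = float(np.mean([np.mean(x) for x in faces]))
    interp = RegularGridInterpolator(
        volume.axes, volume.field, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    vals = interp(pts)
    outside = ~np.isfinite(vals)
    vals = np.where(outside, boundary_value, vals)
    if single:
        return float(vals[0]), bool(outside[0])
    return vals, outside


def orthogonal_distance(
    axis_point,
    isotherm_vertex,
    frame: SliceFrame,
    atol: float = 1e-6,
) -> float:
    """In-plane radial distance (mm) from an axis point to an isotherm vertex.

    The vertex must lie in the image row corresponding to the axial position
    of ``axis_point`` (one-vertex-per-row pairing).
    """
    row, col = float(isotherm_vertex[0]), float(isotherm_vertex[1])
    rc = world_to_slice(frame, np.asarray(axis_point, float))
    if abs(rc[0] - row) > atol:
        raise ValueError(
            f"axis point maps to row {rc[0]:.6f}, vertex is in row {row}"
        )
    return abs(col - frame.axis_column) * frame.pixel_spacing
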