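"""Oblique reslicing of 3D label volumes along long-axis planes.

A cine study is a time-ordered stack of integer label volumes (0 =
background, 1 = LV blood pool, 2 = LA blood pool) sharing a single
voxel-to-world affine.  A long-axis view (2CH/3CH/4CH) is a plane given
by an origin and two orthonormal in-plane direction vectors in world
(mm) coordinates.  Reslicing samples the labels on a regular 2D grid in
that plane with nearest-neighbour lookup: a world point belongs to the
voxel whose centre is nearest (voxel indices are 0-based and the affine
maps voxel *centres* to world coordinates).  Labels are never
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LABEL_BG = 0
LABEL_LV = 1
LABEL_LA = 2

VIEW_TAGS = ("2CH", "3CH", "4CH")


@dataclass
class CineSegmentation:
    """Time-resolved left-heart label segmentation.

    Parameters
    ----------
    frames : list of ndarray
        One 3D integer label grid per cardiac phase; all frames share
        shape.  Labels are 0 (background), 1 (LV blood pool), 2 (LA
        blood pool).
    affine : (4, 4) ndarray
        Voxel-index -> world (mm) transform, voxel-centre convention.
    phase_fractions : sequence of float, optional
        Phase timing as %RR per frame; defaults to a uniform grid.
    """

    frames: list
    affine: np.ndarray
    phase_fractions: list = field(default=None)

    def __post_init__(self):
        self.frames = [np.asarray(f) for f in self.frames]
        if len(self.frames) < 2:
            raise ValueError("a cine segmentation needs at least 2 phases")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValueError(f"frame {i} shape {f.shape} != {shape}")
            labels = np.unique(f)
            if not np.isin(labels, (LABEL_BG, LABEL_LV, LABEL_LA)).all():
                raise ValueError(f"frame {i} carries labels outside {{0,1,2}}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.phase_fractions is None:
            n = len(self.frames)
            self.phase_fractions = [100.0 * i / n for i in range(n)]

    @property
    def n_phases(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames[0].shape

    @property
    def voxel_spacing(self) -> np.ndarray:
        """Per-axis voxel spacing (mm) from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def lv_volumes_ml(self) -> np.ndarray:
        """3D LV blood-pool volume per phase, in mL."""
        vv = self.voxel_volume_mm3
        return np.array(
            [(f == LABEL_LV).sum() * vv / 1000.0 for f in self.frames]
        )


@dataclass
class PlaneDefinition:
    """A long-axis imaging plane: origin + two in-plane unit vectors."""

    view: str
    origin_mm: np.ndarray
    x_dir: np.ndarray
    y_dir: np.ndarray

    def __post_init__(self):
        if self.view not in VIEW_TAGS:
            raise ValueError(f"view must be one of {VIEW_TAGS}, got {self.view!r}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.x_dir = np.asarray(self.x_dir, dtype=float)
        self.y_dir = np.asarray(self.y_dir, dtype=float)
        for name, v in (("x_dir", self.x_dir), ("y_dir", self.y_dir)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} is not unit-norm")
        if abs(float(self.x_dir @ self.y_dir)) > 1e-6:
            raise ValueError("plane direction vectors are not orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.x_dir, self.y_dir)


@dataclass
class LaxSlice:
    """A 2D label slice extracted along a long-axis plane."""

    labels: np.ndarray
    pixel_spacing: float
    view: str = "?"
    phase: int = -1
    empty_warning: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be > 0")

    @property
    def lv_mask(self) -> np.ndarray:
        return self.labels == LABEL_LV

    @property
    def la_mask(self) -> np.ndarray:
        return self.labels == LABEL_LA

    def lv_area_mm2(self) -> float:
        return float(self.lv_mask.sum()) * self.pixel_spacing**2


def reslice(
    volume: np.ndarray,
    affine: np.ndarray,
    plane: PlaneDefinition,
    pixel_spacing: float | None = None,
    extent_mm: float | tuple = 160.0,
    phase: int = -1,
) -> LaxSlice:
    """Extract a 2D label slice from a 3D label volume along a plane.

    The output grid is centred on ``plane.origin_mm`` and spans
    ``extent_mm`` along each in-plane direction.  Each output pixel
    carries the label of the voxel whose centre is nearest to the
    pixel's world-space point; points outside the volume are background.

    Parameters
    ----------
    volume : 3D int array
    affine : (4,4) voxel->world transform (voxel-centre convention)
    plane : PlaneDefinition with orthonormal direction vectors
    pixel_spacing : isotropic output spacing in mm; defaults to the
        smallest voxel dimension (no resolution loss at the boundary).
    extent_mm : physical width of the slice (scalar or (x, y) pair).
    """
    affine = np.asarray(affine, dtype=float)
    if pixel_spacing is None:
        pixel_spacing = float(np.linalg.norm(affine[:3, :3], axis=0).min())
    if np.isscalar(extent_mm):
        extent_mm = (float(extent_mm), float(extent_mm))
    nx = max(2, int(round(extent_mm[0] / pixel_spacing)) + 1)
    ny = max(2, int(round(extent_mm[1] / pixel_spacing)) + 1)

    # world coordinates of every output pixel centre
    u = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    v = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = (
        plane.origin_mm[None, None, :]
        + uu[..., None] * plane.x_dir[None, None, :]
        + vv[..., None] * plane.y_dir[None, None, :]
    )

    # world -> voxel index, nearest-centre rounding
    inv = np.linalg.inv(affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = np.round(ijk).astype(np.int64)

    inside = np.ones(idx.shape[:2], dtype=bool)
    for ax in range(3):
        inside &= (idx[..., ax] >= 0) & (idx[..., ax] < volume.shape[ax])

    out = np.zeros((nx, ny), dtype=volume.dtype)
    ii = idx[inside]
    out[inside] = volume[ii[:, 0], ii[:, 1], ii[:, 2]]

    empty = not out.any()
    if empty:
        warnings.warn(
            f"plane {plane.view} does not intersect any labelled voxel",
            stacklevel=2,
        )
    return LaxSlice(
        labels=out,
        pixel_spacing=pixel_spacing,
        view=plane.view,
        phase=phase,
        empty_warning=empty,
    )


def reslice_cine(
    cine: CineSegmentation,
    plane: PlaneDefinition,
    pixel_spacing: float | None = None,
    extent_mm: float | tuple = 160.0,
) -> list:
    """Reslice every phase of a cine study along one plane."""
    return [
        reslice(frame, cine.affine, plane, pixel_spacing, extent_mm, phase=t)
        for t, frame in enumerate(cine.frames)
    ]
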