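"""Volumetric mask data model and metric morphology primitives.

Every quantity downstream of this module (margins, safety envelopes,
octant localization) is a physical distance in millimetres measured on
anisotropic CT grids, so the primitives here carry voxel spacing
explicitly and use the exact Euclidean metric — never a voxel-count
approximation.

Conventions
-----------
* Volumes are reoriented to the canonical RAS+ anatomical frame at load
  time (axis 0 = left->right, axis 1 = posterior->anterior, axis 2 =
  inferior->superior), so grid axes coincide with the anatomical
  left-right, anterior-posterior and cranio-caudal directions used for
  octant localization.
* Voxel indices are 0-based; physical positions refer to voxel centers;
  distances are measured between voxel centers.
* Masks are interpreted as binary by thresholding stored values at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AnnotatedVolume",
    "ScalarField",
    "load_mask",
    "save_mask",
    "distance_map",
    "dilate_mm",
    "volume_mm3",
]

#: Canonical anatomical axis labels for grid axes 0, 1, 2 (RAS+).
CANONICAL_AXES = ("R", "A", "S")

#: Threshold above which a stored voxel value counts as occupied.
BINARY_THRESHOLD = 0.5


class FormatError(ValueError):
    """Input volume is not a usable 3D mask."""


class MetadataError(ValueError):
    """Volume metadata (affine/spacing) is missing or degenerate."""


class AlignmentError(ValueError):
    """Two volumes expected on the same grid are not."""


@dataclass(frozen=True)
class AnnotatedVolume:
    """A 3D binary occupancy grid with physical geometry.

    Parameters
    ----------
    grid
        Boolean occupancy array, one entry per voxel.
    spacing
        Physical size of a voxel along each grid axis, in mm. All
        components must be positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    orientation
        Anatomical direction of each grid axis, as a signed permutation
        of ``("R", "A", "S")``; canonical volumes use exactly that
        tuple.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise FormatError(f"mask must be 3D, got {grid.ndim}D")
        if min(grid.shape) < 1:
            raise FormatError("mask must have at least one voxel per axis")
        object.__setattr__(self, "grid", grid.astype(bool, copy=False))
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MetadataError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        bare = tuple(a.lstrip("-") for a in self.orientation)
        if sorted(bare) != sorted(CANONICAL_AXES):
            raise MetadataError(
                f"orientation must be a signed permutation of {CANONICAL_AXES}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinate (mm) of voxel-center(s) at ``index``."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel index of physical point(s) in mm."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def same_grid(self, other: "AnnotatedVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.orientation == other.orientation
        )

    def require_same_grid(self, other: "AnnotatedVolume") -> None:
        if not self.same_grid(other):
            raise AlignmentError(
                "masks are not on the same grid "
                f"({self.shape}@{self.spacing} vs {other.shape}@{other.spacing})"
            )

    def with_grid(self, grid: np.ndarray) -> "AnnotatedVolume":
        """Copy of this volume carrying a different occupancy grid."""
        return replace(self, grid=grid)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical (mm) affine, canonical frame."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class ScalarField:
    """A real-valued field (mm) on the grid of a parent :class:`AnnotatedVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise FormatError("scalar field must be 3D")
        object.__setattr__(self, "values", values)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mask(path: str | Path) -> AnnotatedVolume:
    """Load a NIfTI mask and reorient it to the canonical RAS+ frame.

    Voxel values are binarized at 0.5; spacing and origin are taken from
    the affine after reorientation. An empty (all-background) mask loads
    with a warning, not an error.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3D volume, got shape {img.shape}")
    affine = img.affine
    if affine is None or not np.isfinite(affine).all():
        raise MetadataError("missing or non-finite affine")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise MetadataError("degenerate affine: zero voxel volume")
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj)
    grid = data > BINARY_THRESHOLD
    aff = canonical.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff[:3, :3])))
    origin = tuple(float(o) for o in aff[:3, 3])
    vol = AnnotatedVolume(grid=grid, spacing=spacing, origin=origin)
    if vol.is_empty():
        warnings.warn(f"loaded mask {path} is empty", stacklevel=2)
    return vol


def save_mask(vol: AnnotatedVolume, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI with its canonical affine."""
    img = nib.Nifti1Image(vol.grid.astype(np.uint8), vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def distance_map(
    vol: AnnotatedVolume, side: Literal["inside", "outside"]
) -> ScalarField:
    """Exact anisotropic Euclidean distance to the complementary region.

    ``side="outside"``: each voxel holds the distance in mm from its
    center to the nearest *occupied* voxel center (0 inside the mask).
    ``side="inside"``: distance to the nearest *unoccupied* voxel center
    (0 outside the mask). If the target region is absent everywhere the
    field is +inf.
    """
    if side not in ("inside", "outside"):
        raise ValueError(f"side must be 'inside' or 'outside', got {side!r}")
    target = vol.grid if side == "outside" else ~vol.grid
    if not target.any():
        values = np.full(vol.shape, np.inf)
    else:
        # distance_transform_edt measures, at each nonzero voxel, the exact
        # Euclidean distance to the nearest zero voxel (center-to-center),
        # honouring per-axis sampling.
        values = ndimage.distance_transform_edt(~target, sampling=vol.spacing)
    return ScalarField(
        values=values,
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
    )


def dilate_mm(vol: AnnotatedVolume, r: float) -> AnnotatedVolume:
    """Metric dilation: all voxels within ``r`` mm of the mask.

    Implemented by thresholding the outside distance map, so the result
    is exact under the voxel-center metric regardless of anisotropy.
    ``r=0`` returns the input unchanged.
    """
    if r < 0:
        raise ValueError(f"dilation radius must be >= 0, got {r}")
    if r == 0:
        return vol
    dist = distance_map(vol, side="outside")
    return vol.with_grid(dist.values <= r)


def volume_mm3(vol: AnnotatedVolume) -> float:
    """Occupied volume: voxel count times voxel volume (mm^3)."""
    return float(np.count_nonzero(vol.grid)) * vol.voxel_volume
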