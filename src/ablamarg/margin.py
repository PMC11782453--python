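"""Minimal ablative margin (MAM) quantification.

The minimal ablative margin is the smallest 3D distance between the
boundary of the ablated tumor and the boundary of the coagulation zone.
Two software-style definitions are implemented, both operating on
co-registered binary masks:

coverage MAM (Ablation-fit style)
    For each integer safety margin r = 1..10 mm, the *unablated volume*
    is the part of the tumor dilated by r mm that falls outside the
    ablation zone. The MAM is the largest r whose unablated volume is
    zero. Tumors not fully covered at r = 0 are classed ``residual``
    (MAM < 0); margins beyond 10 mm are reported as 10 because the
    definition does not resolve them.

surface MAM (SAFIR style)
    The signed distance from each tumor voxel to the ablation-zone
    boundary (positive inside the zone, negative outside), minimised
    over the tumor and rounded to the nearest millimetre, half away
    from zero. Negative values indicate incomplete coverage.

Octant localization documents on which side(s) of the tumor an
insufficient margin (< 5 mm) occurs: tumor voxels are partitioned into
eight octants by the three anatomical planes (left-right,
anterior-posterior, cranio-caudal) through the tumor centroid, and the
surface-MAM minimum is taken per octant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .registration import (
    LandmarkSet,
    RegistrationAudit,
    apply_transform,
    audit_registration,
    fit_rigid,
)
from .volumes import AnnotatedVolume, distance_map

__all__ = [
    "RESIDUAL",
    "MarginResult",
    "RegistrationExcluded",
    "residual_tumor",
    "mam_coverage",
    "mam_surface",
    "octant_margins",
    "quantify",
]

#: Sentinel category for incomplete tumor coverage under the coverage definition.
RESIDUAL = "residual"

#: Safety margins (mm) swept by the coverage definition.
COVERAGE_MARGINS_MM = tuple(range(1, 11))

#: Margins below this value (mm) are flagged as insufficient per octant.
INSUFFICIENT_MARGIN_MM = 5.0

#: Octant keys: sign of (left-right, anterior-posterior, cranio-caudal)
#: offset from the tumor centroid, in canonical RAS+ order.
OCTANT_KEYS = tuple(
    f"{sr}R{sa}A{ss}S" for sr in "+-" for sa in "+-" for ss in "+-"
)


class RegistrationExcluded(RuntimeError):
    """Raised when the co-registration audit fails and the case is excluded."""

    def __init__(self, audit: RegistrationAudit):
        self.audit = audit
        super().__init__(
            "excluded: failed co-registration "
            f"({audit.n_mismatches} landmarks mismatch > 3 mm)"
        )


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class MarginResult:
    """Per-tumor margin summary under both MAM definitions.

    ``mam_coverage`` is an integer 0..10 or the string ``"residual"``.
    ``mam_sentinel`` maps that onto the signed integer scale used by
    threshold analyses: −1 for residual, otherwise ``mam_coverage``.
    ``mam_surface`` is the signed integer surface MAM;
    ``mam_surface_unrounded`` keeps the sub-millimetre value for
    convergence analyses.
    """

    mam_coverage: int | str
    mam_surface: int
    mam_surface_unrounded: float
    unablated_volume_by_margin: dict[int, float]
    residual_volume: float
    octant_min_margin: dict[str, int]
    insufficient_octants: tuple[str, ...]
    registration_audit: RegistrationAudit | None = None

    @property
    def mam_sentinel(self) -> int:
        return -1 if self.mam_coverage == RESIDUAL else int(self.mam_coverage)

    def to_dict(self) -> dict:
        return {
            "mam_coverage": self.mam_coverage,
            "mam_sentinel": self.mam_sentinel,
            "mam_surface": self.mam_surface,
            "mam_surface_unrounded": self.mam_surface_unrounded,
            "residual_volume_mm3": self.residual_volume,
            "unablated_volume_by_margin_mm3": {
                str(r): v for r, v in self.unablated_volume_by_margin.items()
            },
            "octant_min_margin_mm": dict(self.octant_min_margin),
            "insufficient_octants": list(self.insufficient_octants),
        }


# ---------------------------------------------------------------------------
# Residual tumor and coverage-based MAM
# ---------------------------------------------------------------------------

def residual_tumor(tumor: AnnotatedVolume, ablation: AnnotatedVolume) -> float:
    """Volume (mm^3) of tumor outside the ablation zone.

    Zero iff every tumor voxel lies inside the ablation mask.
    """
    tumor.require_same_grid(ablation)
    return float(np.count_nonzero(tumor.grid & ~ablation.grid)) * tumor.voxel_volume


def mam_coverage(
    tumor: AnnotatedVolume, ablation: AnnotatedVolume
) -> tuple[int | str, dict[int, float]]:
    """Coverage-based MAM and the unablated volume per safety margin.

    For each r in 1..10 mm the r-mm safety envelope is the tumor dilated
    by r; its unablated volume is the part outside the ablation zone.
    MAM is the largest r completely ablated; ``"residual"`` when the
    bare tumor is not fully covered; 0 when the tumor is covered but no
    swept margin is; margins past 10 mm collapse to 10.
    """
    tumor.require_same_grid(ablation)
    if tumor.is_empty():
        raise ValueError("tumor mask is empty")
    # distance-to-tumor thresholding gives every dilation from one EDT
    dist = distance_map(tumor, side="outside").values
    outside = ~ablation.grid
    vox = tumor.voxel_volume
    unablated = {
        r: float(np.count_nonzero((dist <= r) & outside)) * vox
        for r in COVERAGE_MARGINS_MM
    }
    if residual_tumor(tumor, ablation) > 0:
        return RESIDUAL, unablated
    mam = 0
    for r in COVERAGE_MARGINS_MM:
        if unablated[r] == 0:
            mam = r
        else:
            break
    return mam, unablated


# ---------------------------------------------------------------------------
# Surface-distance MAM
# ---------------------------------------------------------------------------

def _ablation_boundary(ablation: AnnotatedVolume) -> np.ndarray:
    """Ablation voxels with at least one face-neighbour outside the mask."""
    eroded = ndimage.binary_erosion(
        ablation.grid,
        structure=ndimage.generate_binary_structure(3, 1),
        border_value=0,
    )
    return ablation.grid & ~eroded


def signed_distance_to_boundary(
    tumor: AnnotatedVolume, ablation: AnnotatedVolume
) -> np.ndarray:
    """Signed distance (mm) of every voxel to the ablation boundary.

    Positive for voxels inside the ablation mask, negative outside;
    distances are measured to boundary voxel centers with the exact
    anisotropic Euclidean metric.
    """
    tumor.require_same_grid(ablation)
    boundary = _ablation_boundary(ablation)
    if not boundary.any():
        raise ValueError("ablation mask is empty")
    dist = ndimage.distance_transform_edt(~boundary, sampling=ablation.spacing)
    return np.where(ablation.grid, dist, -dist)


def mam_surface(
    tumor: AnnotatedVolume, ablation: AnnotatedVolume
) -> tuple[int, float]:
    """Surface-distance MAM: minimum signed distance over tumor voxels.

    Returns ``(rounded, unrounded)`` where ``rounded`` is the signed
    integer MAM (nearest mm, half away from zero).
    """
    if tumor.is_empty():
        raise ValueError("tumor mask is empty")
    signed = signed_distance_to_boundary(tumor, ablation)
    unrounded = float(signed[tumor.grid].min())
    return _round_half_away(unrounded), unrounded


# ---------------------------------------------------------------------------
# Octant localization
# ---------------------------------------------------------------------------

def octant_margins(
    tumor: AnnotatedVolume, ablation: AnnotatedVolume
) -> tuple[dict[str, int], tuple[str, ...]]:
    """Per-octant minimal margins and the set with insufficient (< 5 mm) margin.

    Tumor voxels are split into octants by the three anatomical planes
    through the tumor centroid (center of mass of tumor voxels, physical
    coordinates); voxels lying exactly on a plane go to the ``+`` side.
    Empty octants are omitted.
    """
    if tumor.is_empty():
        raise ValueError("tumor mask is empty")
    signed = signed_distance_to_boundary(tumor, ablation)
    idx = np.argwhere(tumor.grid)
    coords = tumor.index_to_physical(idx)
    centroid = coords.mean(axis=0)
    offsets = coords - centroid
    values = signed[tumor.grid]

    margins: dict[str, int] = {}
    insufficient: list[str] = []
    neg = offsets < 0  # (n, 3); False -> "+" side (ties included)
    for key in OCTANT_KEYS:
        want_neg = np.array([key[0] == "-", key[2] == "-", key[4] == "-"])
        members = (neg == want_neg).all(axis=1)
        if not members.any():
            continue
        octant_min = float(values[members].min())
        rounded = _round_half_away(octant_min)
        margins[key] = rounded
        if rounded < INSUFFICIENT_MARGIN_MM:
            insufficient.append(key)
    return margins, tuple(insufficient)


# ---------------------------------------------------------------------------
# Composite quantification
# ---------------------------------------------------------------------------

def quantify(
    tumor: AnnotatedVolume,
    ablation: AnnotatedVolume,
    landmarks: LandmarkSet | None = None,
) -> MarginResult:
    """Full per-tumor margin quantification.

    When landmarks are given, a rigid transform is fitted, audited
    against the >3 mm mismatch rule, and used to resample the
    (pre-scan) tumor mask onto the ablation grid; an insufficient audit
    excludes the case by raising :class:`RegistrationExcluded`. Without
    landmarks the masks must already share a grid.
    """
    audit = None
    if landmarks is not None:
        transform = fit_rigid(landmarks)
        audit = audit_registration(landmarks, transform)
        if not audit.sufficient:
            raise RegistrationExcluded(audit)
        tumor = apply_transform(tumor, transform, reference=ablation)
    tumor.require_same_grid(ablation)

    residual = residual_tumor(tumor, ablation)
    coverage, unablated = mam_coverage(tumor, ablation)
    surface_rounded, surface_raw = mam_surface(tumor, ablation)
    octants, insufficient = octant_margins(tumor, ablation)
    return MarginResult(
        mam_coverage=coverage,
        mam_surface=surface_rounded,
        mam_surface_unrounded=surface_raw,
        unablated_volume_by_margin=unablated,
        residual_volume=residual,
        octant_min_margin=octants,
        insufficient_octants=insufficient,
        registration_audit=audit,
    )
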