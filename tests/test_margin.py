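"""Both MAM definitions, octant localization, and the composite quantification."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ablamarg import (
    RESIDUAL,
    LandmarkSet,
    RegistrationExcluded,
    make_phantom,
    mam_coverage,
    mam_surface,
    octant_margins,
    quantify,
    residual_tumor,
)
from ablamarg.margin import _round_half_away
from ablamarg.synthetic import PhantomSpec, ShapeSpec
from ablamarg.volumes import AlignmentError

from conftest import make_vol, random_blob


def sphere_pair(r_tumor, r_ablation, spacing=1.0, offset=(0.0, 0.0, 0.0)):
    spec = PhantomSpec(
        tumor=ShapeSpec.sphere((0.0, 0.0, 0.0), r_tumor),
        ablation=ShapeSpec.sphere(offset, r_ablation),
        spacing=(spacing,) * 3,
    )
    tumor, ablation, _, truth = make_phantom(spec)
    return tumor, ablation, truth


def brute_force_surface_mam(tumor, ablation):
    """Independent signed minimum: pairwise distances to face-boundary voxels."""
    grid = ablation.grid
    interior = grid.copy()
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(grid, shift, axis=axis)
            edge = np.zeros_like(grid)
            idx = [slice(None)] * 3
            idx[axis] = 0 if shift == 1 else -1
            rolled[tuple(idx)] = False  # outside the grid counts as background
            interior &= rolled
    boundary = grid & ~interior
    sp = np.asarray(ablation.spacing)
    bpts = np.argwhere(boundary) * sp
    tpts = np.argwhere(tumor.grid) * sp
    dist = cdist(tpts, bpts).min(axis=1)
    sign = np.where(grid[tumor.grid], 1.0, -1.0)
    return (sign * dist).min()


class TestResidualTumor:
    def test_subset_gives_zero(self):
        tumor, ablation, _ = sphere_pair(5, 9)
        assert residual_tumor(tumor, ablation) == 0.0

    def test_concentric_shell_volume(self):
        tumor, ablation, _ = sphere_pair(10, 8)
        analytic = 4 / 3 * np.pi * (10**3 - 8**3)
        assert residual_tumor(tumor, ablation) == pytest.approx(analytic, rel=0.10)

    def test_disjoint_gives_full_tumor_volume(self):
        tumor = make_vol(np.pad(np.ones((3, 3, 3), bool), ((0, 7),) * 3))
        ablation = make_vol(np.pad(np.ones((3, 3, 3), bool), ((7, 0),) * 3))
        assert residual_tumor(tumor, ablation) == 27.0

    def test_grid_mismatch_rejected(self):
        tumor = make_vol(np.ones((4, 4, 4), bool))
        ablation = make_vol(np.ones((4, 4, 4), bool), spacing=(2, 2, 2))
        with pytest.raises(AlignmentError):
            residual_tumor(tumor, ablation)


class TestCoverageMam:
    def test_concentric_closed_form(self):
        tumor, ablation, _ = sphere_pair(10, 15, spacing=0.5)
        mam, unablated = mam_coverage(tumor, ablation)
        assert mam == 5
        assert unablated[5] == 0 and unablated[6] > 0

    def test_offset_closed_form(self):
        tumor, ablation, _ = sphere_pair(8, 14, offset=(2.0, 0.0, 0.0), spacing=0.5)
        mam, _ = mam_coverage(tumor, ablation)
        assert mam == 4

    def test_incomplete_coverage_is_residual(self):
        tumor, ablation, _ = sphere_pair(10, 8)
        mam, _ = mam_coverage(tumor, ablation)
        assert mam == RESIDUAL

    def test_unablated_volume_nondecreasing(self, rng):
        tumor = make_vol(random_blob(rng, (24, 24, 24), radius_range=(2, 4)))
        ablation = make_vol(random_blob(rng, (24, 24, 24), radius_range=(4, 8)))
        _, unablated = mam_coverage(tumor, ablation)
        vols = [unablated[r] for r in range(1, 11)]
        assert all(a <= b for a, b in zip(vols, vols[1:]))

    def test_large_margin_collapses_to_ten(self):
        tumor, ablation, _ = sphere_pair(3, 18, spacing=1.0)
        mam, _ = mam_coverage(tumor, ablation)
        assert mam == 10

    def test_empty_tumor_rejected(self):
        empty = make_vol(np.zeros((6, 6, 6), bool))
        full = make_vol(np.ones((6, 6, 6), bool))
        with pytest.raises(ValueError):
            mam_coverage(empty, full)


class TestSurfaceMam:
    def test_concentric_positive(self):
        tumor, ablation, _ = sphere_pair(10, 15, spacing=0.5)
        rounded, raw = mam_surface(tumor, ablation)
        assert rounded == 5
        assert raw == pytest.approx(5.0, abs=0.5 * np.sqrt(3))

    def test_concentric_negative(self):
        tumor, ablation, _ = sphere_pair(10, 8, spacing=0.5)
        rounded, _ = mam_surface(tumor, ablation)
        assert rounded == -2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        spacing = (1.0, 1.0, 2.0) if seed % 2 else (1.0, 1.0, 1.0)
        tumor = make_vol(random_blob(rng, (24, 24, 24), radius_range=(2, 5), spacing=spacing), spacing=spacing)
        ablation = make_vol(random_blob(rng, (24, 24, 24), radius_range=(4, 9), spacing=spacing), spacing=spacing)
        if tumor.is_empty() or ablation.is_empty():
            pytest.skip("degenerate draw")
        _, raw = mam_surface(tumor, ablation)
        assert raw == pytest.approx(brute_force_surface_mam(tumor, ablation), abs=1e-9)

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(0.5) == 1
        assert _round_half_away(-0.5) == -1
        assert _round_half_away(2.49) == 2
        assert _round_half_away(-1.5) == -2
        assert _round_half_away(0.0) == 0


class TestOctants:
    def test_concentric_symmetry(self):
        tumor, ablation, _ = sphere_pair(10, 15, spacing=0.5)
        margins, insufficient = octant_margins(tumor, ablation)
        assert len(margins) == 8
        assert set(margins.values()) == {5}
        assert insufficient == ()

    def test_offset_ablation_localizes_thin_side(self):
        # ablation shifted +3 mm along left-right: thin margins on the -R side.
        # closed form: -R octant min = R_a - (R_t + 3) = 3 mm (at the -R pole);
        # +R octant min = R_a - sqrt(3^2 + R_t^2) = 5.56 mm (at the equator).
        tumor, ablation, _ = sphere_pair(10, 16, offset=(3.0, 0.0, 0.0), spacing=0.5)
        margins, insufficient = octant_margins(tumor, ablation)
        neg_side = {k: v for k, v in margins.items() if k.startswith("-")}
        pos_side = {k: v for k, v in margins.items() if k.startswith("+")}
        assert all(v == pytest.approx(3, abs=1) for v in neg_side.values())
        assert all(v == pytest.approx(16 - np.hypot(3, 10), abs=1) for v in pos_side.values())
        assert set(insufficient) == set(neg_side)

    @pytest.mark.parametrize("seed", range(4))
    def test_min_octant_equals_global_mam(self, seed):
        rng = np.random.default_rng(seed)
        tumor = make_vol(random_blob(rng, (20, 20, 20), radius_range=(2, 5)))
        ablation = make_vol(random_blob(rng, (20, 20, 20), radius_range=(4, 8)))
        if tumor.is_empty() or ablation.is_empty():
            pytest.skip("degenerate draw")
        margins, _ = octant_margins(tumor, ablation)
        rounded, _ = mam_surface(tumor, ablation)
        assert min(margins.values()) == rounded


class TestQuantify:
    def test_composed_result_on_registered_phantom(self):
        tumor, ablation, _ = sphere_pair(10, 15, spacing=0.5)
        result = quantify(tumor, ablation)
        assert result.mam_coverage == 5
        assert result.mam_surface == 5
        assert result.mam_sentinel == 5
        assert result.insufficient_octants == ()
        assert result.residual_volume == 0.0

    def test_residual_phantom_sentinel(self):
        tumor, ablation, _ = sphere_pair(10, 8)
        result = quantify(tumor, ablation)
        assert result.mam_coverage == RESIDUAL
        assert result.mam_sentinel == -1
        assert result.mam_surface < 0
        assert result.residual_volume > 0

    def test_failed_registration_audit_excludes_case(self):
        tumor, ablation, _ = sphere_pair(5, 9)
        # opposite 10 mm perturbations that no rigid fit can absorb: the
        # least-squares residuals leave more than one landmark > 3 mm off
        pre = np.array(
            [[0, 0, 0], [20, 0, 0], [0, 20, 0], [0, 0, 20], [20, 20, 0]], float
        )
        post = pre.copy()
        post[0, 1] += 10.0
        post[1, 1] -= 10.0
        landmarks = LandmarkSet(labels=("a", "b", "c", "d", "e"), pre=pre, post=post)
        with pytest.raises(RegistrationExcluded, match="failed co-registration"):
            quantify(tumor, ablation, landmarks=landmarks)

    def test_growing_ablation_never_decreases_mam(self, rng):
        tumor, ablation, _ = sphere_pair(6, 9, spacing=1.0)
        from ablamarg import dilate_mm

        bigger = dilate_mm(ablation, 2.0)
        before = quantify(tumor, ablation)
        after = quantify(tumor, bigger)
        assert after.mam_sentinel >= before.mam_sentinel
        assert after.mam_surface >= before.mam_surface

    def test_definitions_agree_on_covered_convex_phantoms(self):
        for r_t, r_a in [(5.0, 8.2), (6.0, 12.7), (4.0, 9.9)]:
            tumor, ablation, truth = sphere_pair(r_t, r_a, spacing=0.5)
            result = quantify(tumor, ablation)
            clamped = int(np.clip(np.floor(result.mam_surface_unrounded), 0, 10))
            assert abs(result.mam_coverage - clamped) <= 1
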