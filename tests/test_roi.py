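"""Region morphology against brute-force physical-distance oracles."""

import numpy as np
import pytest

from bcrfusion.io_data import GridMismatchError, MaskLabel, SegmentationMask
from bcrfusion.roi import build_regions, dice, dilate_mm

rng = np.random.default_rng(7)


def brute_force_dilate(mask: np.ndarray, spacing, radius: float) -> np.ndarray:
    """O(n*m) oracle: voxel centers within `radius` mm of any set voxel."""
    set_idx = np.argwhere(mask > 0).astype(float) * np.asarray(spacing)
    coords = np.indices(mask.shape).reshape(3, -1).T.astype(float) * np.asarray(spacing)
    d2 = ((coords[:, None, :] - set_idx[None, :, :]) ** 2).sum(-1).min(axis=1)
    return (d2 <= radius**2 + 1e-9).reshape(mask.shape).astype(np.uint8)


def _mask(grid, spacing=(1.0, 1.0, 1.0), label=MaskLabel.TUMOR):
    return SegmentationMask(grid.astype(np.uint8), spacing, label)


def test_single_voxel_isotropic_radius2_sets_33_voxels():
    g = np.zeros((7, 7, 7))
    g[3, 3, 3] = 1
    out = dilate_mm(_mask(g), 2.0)
    assert int(out.grid.sum()) == 33
    assert np.array_equal(out.grid, brute_force_dilate(g, (1, 1, 1), 2.0))


def test_single_voxel_anisotropic_radius2_stays_in_plane():
    g = np.zeros((5, 7, 7))
    g[2, 3, 3] = 1
    out = dilate_mm(_mask(g, spacing=(3.0, 1.0, 1.0)), 2.0)
    assert int(out.grid.sum()) == 13
    assert out.grid[[0, 1, 3, 4]].sum() == 0  # nothing leaves the axial plane
    assert np.array_equal(out.grid, brute_force_dilate(g, (3, 1, 1), 2.0))


def test_radius_zero_is_identity_and_negative_rejected():
    g = (rng.random((6, 6, 6)) < 0.2).astype(np.uint8)
    g[3, 3, 3] = 1
    m = _mask(g)
    assert np.array_equal(dilate_mm(m, 0.0).grid, g)
    with pytest.raises(ValueError):
        dilate_mm(m, -1.0)


@pytest.mark.parametrize("seed", range(10))
def test_dilation_matches_brute_force_oracle_random_masks(seed):
    r = np.random.default_rng(seed)
    shape = tuple(r.integers(4, 25, size=3))
    spacing = tuple(r.uniform(0.5, 4.0, size=3))
    g = (r.random(shape) < 0.05).astype(np.uint8)
    if not g.any():
        g[tuple(s // 2 for s in shape)] = 1
    radius = float(r.uniform(0.5, 6.0))
    out = dilate_mm(_mask(g, spacing), radius)
    assert np.array_equal(out.grid, brute_force_dilate(g, spacing, radius))


def test_dilation_monotone_in_radius():
    g = (rng.random((10, 10, 10)) < 0.05).astype(np.uint8)
    g[5, 5, 5] = 1
    m = _mask(g, spacing=(2.0, 0.7, 0.7))
    prev = dilate_mm(m, 0.0).grid
    for r in (1.0, 2.5, 4.0):
        cur = dilate_mm(m, r).grid
        assert np.all(prev <= cur)
        prev = cur


def _ball(shape, spacing, center_mm, radius_mm):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    z, y, x = np.meshgrid(*ax, indexing="ij", sparse=True)
    return (((z - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
             + (x - center_mm[2]) ** 2) <= radius_mm**2)


def test_build_regions_matches_set_algebra_oracle():
    shape, spacing = (24, 24, 24), (1.0, 1.0, 1.0)
    prostate = _ball(shape, spacing, (12, 12, 12), 10.0)
    tumor = _ball(shape, spacing, (12, 12, 12), 5.0)
    regions = build_regions(_mask(tumor), _mask(prostate, label=MaskLabel.PROSTATE),
                            margin_mm=5.0)
    dil_t = brute_force_dilate(tumor.astype(np.uint8), spacing, 5.0).astype(bool)
    dil_p = brute_force_dilate(prostate.astype(np.uint8), spacing, 5.0).astype(bool)
    assert np.array_equal(regions.itr.grid.astype(bool), tumor)
    assert np.array_equal(regions.ptr.grid.astype(bool), dil_t & prostate & ~tumor)
    assert np.array_equal(regions.ppr.grid.astype(bool), dil_p & ~prostate)
    regions.check_invariants(_mask(prostate, label=MaskLabel.PROSTATE))


def test_build_regions_zero_margin_gives_empty_shells():
    shape, spacing = (16, 16, 16), (1.0, 1.0, 1.0)
    prostate = _ball(shape, spacing, (8, 8, 8), 6.0)
    tumor = _ball(shape, spacing, (8, 8, 8), 3.0)
    regions = build_regions(_mask(tumor), _mask(prostate, label=MaskLabel.PROSTATE),
                            margin_mm=0.0)
    assert regions.ptr.empty and regions.ppr.empty


def test_tumor_touching_surface_keeps_ptr_inside_prostate():
    shape, spacing = (20, 20, 20), (1.0, 1.0, 1.0)
    prostate = _ball(shape, spacing, (10, 10, 10), 8.0)
    tumor = _ball(shape, spacing, (10, 10, 16), 3.0)  # touches the surface
    regions = build_regions(_mask(tumor & prostate),
                            _mask(prostate, label=MaskLabel.PROSTATE), margin_mm=5.0)
    assert not (regions.ptr.grid.astype(bool) & ~prostate).any()


def test_build_regions_applies_exclusion_and_checks_grids():
    shape, spacing = (16, 16, 16), (1.0, 1.0, 1.0)
    prostate = _ball(shape, spacing, (8, 8, 8), 5.0)
    tumor = _ball(shape, spacing, (8, 8, 8), 2.0)
    excl = _ball(shape, spacing, (8, 14, 8), 3.0) & ~prostate
    regions = build_regions(_mask(tumor), _mask(prostate, label=MaskLabel.PROSTATE),
                            _mask(excl, label=MaskLabel.ORGAN_EXCLUSION), 5.0)
    assert not (regions.ppr.grid.astype(bool) & excl).any()
    with pytest.raises(GridMismatchError):
        build_regions(_mask(np.zeros((4, 4, 4))), _mask(prostate, label=MaskLabel.PROSTATE))


def test_region_invariants_hold_on_synthetic_cohort(small_cohort):
    for p in small_cohort.patients:
        regions = build_regions(p.tumor, p.prostate, p.exclusion, 5.0)
        regions.check_invariants(p.prostate)


def test_dice_values_and_symmetry():
    a = np.zeros((4, 4, 4)); a[0, 0, :4] = 1
    b = np.zeros((4, 4, 4)); b[0, 0, 2:4] = 1; b[0, 1, :2] = 1
    ma, mb = _mask(a), _mask(b)
    assert dice(ma, ma) == 1.0
    assert dice(ma, mb) == pytest.approx(0.5)
    assert dice(ma, mb) == dice(mb, ma)
    c = np.zeros((4, 4, 4)); c[3, 3, 3] = 1
    assert dice(ma, _mask(c)) == 0.0
    with pytest.raises(ValueError):
        dice(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 4))))


from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=hnp.arrays(np.int8, (5, 5, 5), elements=st.integers(0, 1)),
    b=hnp.arrays(np.int8, (5, 5, 5), elements=st.integers(0, 1)),
)
def test_dice_symmetric_and_bounded(a, b):
    if not (a.any() or b.any()):
        a[2, 2, 2] = 1
    ma, mb = _mask(a.astype(np.uint8)), _mask(b.astype(np.uint8))
    d = dice(ma, mb)
    assert 0.0 <= d <= 1.0
    assert d == dice(mb, ma)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    mask=hnp.arrays(np.int8, (6, 6, 6), elements=st.integers(0, 1)),
    r1=st.floats(0.0, 3.0),
    r2=st.floats(0.0, 3.0),
)
def test_dilation_monotonicity_property(mask, r1, r2):
    if not mask.any():
        mask[3, 3, 3] = 1
    m = _mask(mask.astype(np.uint8), spacing=(2.0, 0.8, 0.8))
    lo, hi = sorted((r1, r2))
    assert np.all(dilate_mm(m, lo).grid <= dilate_mm(m, hi).grid)
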