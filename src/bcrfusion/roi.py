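"""Construction of the three analysis regions from tumor and prostate masks.

The intratumoral region (ITR) is the tumor mask itself.  The peritumoral
region (PTR) is a millimetre-scale shell around the tumor, clipped to the
prostate and excluding the tumor interior.  The periprostatic region (PPR)
is the shell outside the prostate after dilating its contour, minus any
adjacent-organ exclusion mask.

Dilation is defined by thresholding the exact Euclidean distance transform
computed with the physical voxel spacing, so a "5 mm" margin means 5 mm in
every direction even on anisotropic grids.  Membership is decided at voxel
centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_data import GridMismatchError, MaskLabel, SegmentationMask

__all__ = ["RegionMaskSet", "dilate_mm", "build_regions", "dice", "REGIONS"]

REGIONS = ("ITR", "PTR", "PPR")

# distances are exact sums of squares of spacing multiples; the epsilon only
# guards against float rounding in sqrt, it never admits a farther voxel
_DIST_EPS = 1e-9


@dataclass
class RegionMaskSet:
    """The three disjoint analysis regions on a shared grid."""

    itr: SegmentationMask
    ptr: SegmentationMask
    ppr: SegmentationMask
    margin_mm: float = 5.0

    def __getitem__(self, region: str) -> SegmentationMask:
        return {"ITR": self.itr, "PTR": self.ptr, "PPR": self.ppr}[region.upper()]

    def check_invariants(self, prostate: SegmentationMask | None = None):
        """Raise if the disjointness/containment contracts are violated."""
        i, p, q = self.itr.grid, self.ptr.grid, self.ppr.grid
        if (i & p).any():
            raise AssertionError("ITR and PTR overlap")
        if (p & q).any():
            raise AssertionError("PTR and PPR overlap")
        if (i & q).any():
            raise AssertionError("ITR and PPR overlap")
        if prostate is not None:
            if (p & ~prostate.grid.astype(bool)).any():
                raise AssertionError("PTR extends outside the prostate")
            if (q & prostate.grid.astype(bool)).any():
                raise AssertionError("PPR overlaps the prostate")


def dilate_mm(mask: SegmentationMask, radius_mm: float) -> SegmentationMask:
    """Dilate a binary mask by a physical radius in millimetres.

    A voxel belongs to the output iff its center lies within Euclidean
    distance ``radius_mm`` of the center of some set voxel, with distances
    measured in mm using the mask's (possibly anisotropic) spacing.
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be >= 0, got {radius_mm}")
    if mask.empty or radius_mm == 0:
        return SegmentationMask(mask.grid.copy(), mask.spacing, mask.label)
    dist = ndimage.distance_transform_edt(1 - mask.grid, sampling=mask.spacing)
    out = dist <= radius_mm + _DIST_EPS
    return SegmentationMask(out.astype(np.uint8), mask.spacing, mask.label)


def build_regions(
    tumor: SegmentationMask,
    prostate: SegmentationMask,
    exclusion: SegmentationMask | None = None,
    margin_mm: float = 5.0,
) -> RegionMaskSet:
    """Build ITR/PTR/PPR from tumor and prostate masks.

    ``itr = tumor``;
    ``ptr = (dilate(tumor, margin) ∩ prostate) \\ tumor``;
    ``ppr = (dilate(prostate, margin) \\ prostate) \\ exclusion``.
    Tumor voxels outside the prostate are kept in the ITR but a warning is
    issued, since the segmentation protocol assumes tumor ⊆ prostate.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if tumor.shape != prostate.shape or not np.allclose(tumor.spacing, prostate.spacing):
        raise GridMismatchError(
            f"tumor grid {tumor.shape}/{tumor.spacing} != "
            f"prostate grid {prostate.shape}/{prostate.spacing}"
        )
    if exclusion is not None and exclusion.shape != tumor.shape:
        raise GridMismatchError(
            f"exclusion grid {exclusion.shape} != tumor grid {tumor.shape}"
        )
    t = tumor.grid.astype(bool)
    p = prostate.grid.astype(bool)
    if (t & ~p).any():
        warnings.warn("tumor mask extends outside the prostate mask", stacklevel=2)
    ptr = dilate_mm(tumor, margin_mm).grid.astype(bool) & p & ~t
    ppr = dilate_mm(prostate, margin_mm).grid.astype(bool) & ~p
    if exclusion is not None:
        ppr &= ~exclusion.grid.astype(bool)
    sp = tumor.spacing
    return RegionMaskSet(
        itr=SegmentationMask(t.astype(np.uint8), sp, MaskLabel.TUMOR),
        ptr=SegmentationMask(ptr.astype(np.uint8), sp, MaskLabel.TUMOR),
        ppr=SegmentationMask(ppr.astype(np.uint8), sp, MaskLabel.PROSTATE),
        margin_mm=margin_mm,
    )


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    if a.shape != b.shape:
        raise GridMismatchError(f"dice: shapes differ {a.shape} vs {b.shape}")
    na = int(a.grid.sum())
    nb = int(b.grid.sum())
    if na + nb == 0:
        raise ValueError("dice undefined: both masks are empty")
    inter = int((a.grid & b.grid).sum())
    return 2.0 * inter / (na + nb)
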