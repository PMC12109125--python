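"""From volumes + region masks + clinical rows to model-ready inputs.

Volumes are z-score normalised per volume.  For each region, the axial
slices intersecting the region are taken as a contiguous span, cropped to
the region's in-plane bounding box (padded by a configurable fraction),
masked so that non-region pixels are exactly zero, resized to a fixed
square input size, and stacked as dual-channel (T2WI-FS, DWI) slice pairs.
A fixed slice budget is enforced: short spans are zero-padded (flagged),
long spans are uniformly subsampled.  Clinical covariates are encoded to a
fixed-length vector in [0, 1]: numerics min–max scaled with statistics from
the *training split only* (out-of-range values at inference are clipped),
ordinal categoricals mapped to (code − 1)/(K − 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .io_data import ClinicalRecord, ClinicalSchema, SegmentationMask, Volume

__all__ = [
    "SlicePair",
    "ClinicalVector",
    "ClinicalStats",
    "AugmentParams",
    "zscore_normalize",
    "extract_slices",
    "fit_clinical_stats",
    "encode_clinical",
    "augment",
]


@dataclass
class SlicePair:
    """One dual-channel, region-masked 2-D slice (H, W, 2)."""

    pixels: np.ndarray
    axial_index: int
    region: str
    is_padding: bool = False

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float32)
        if p.ndim != 3 or p.shape[2] != 2:
            raise ValueError(f"slice pixels must be (H, W, 2), got {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise ValueError(f"slice must be square, got {p.shape[:2]}")
        self.pixels = p


@dataclass
class ClinicalVector:
    values: np.ndarray
    field_names: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or len(v) != len(self.field_names):
            raise ValueError("clinical vector length must match field names")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("clinical vector entries must lie in [0, 1]")
        self.values = v


def zscore_normalize(v: Volume) -> Volume:
    """Whole-volume z-score normalisation (mean 0, SD 1)."""
    g = np.asarray(v.grid, dtype=np.float64)
    sd = g.std()
    if sd == 0:
        raise ValueError(f"constant volume ({v.patient_id}/{v.sequence}): z-score undefined")
    return Volume((g - g.mean()) / sd, v.spacing, v.sequence, v.patient_id)


def _span_indices(first: int, last: int, n_slices: int) -> np.ndarray:
    """Uniformly subsample the inclusive axial span [first, last]."""
    span = last - first + 1
    if span <= n_slices:
        return np.arange(first, last + 1)
    return np.unique(np.round(np.linspace(first, last, n_slices)).astype(int))


def extract_slices(
    t2: Volume,
    dwi: Volume,
    region_mask: SegmentationMask,
    n_slices: int = 8,
    out_size: int = 64,
    region: str = "ITR",
    bbox_pad_fraction: float = 0.1,
) -> list[SlicePair]:
    """Build the fixed-length, masked, resized slice stack for one region."""
    if region_mask.empty:
        raise ValueError(f"region mask for {region} is empty")
    if t2.shape != dwi.shape or t2.shape != region_mask.shape:
        raise ValueError(
            f"grids differ: t2 {t2.shape}, dwi {dwi.shape}, mask {region_mask.shape}"
        )
    m = region_mask.grid.astype(bool)
    ax_any = np.where(m.any(axis=(1, 2)))[0]
    first, last = int(ax_any[0]), int(ax_any[-1])
    # in-plane bounding box over the whole 3-D region, padded by a fraction
    rows = np.where(m.any(axis=(0, 2)))[0]
    cols = np.where(m.any(axis=(0, 1)))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pr = int(round((r1 - r0) * bbox_pad_fraction))
    pc = int(round((c1 - c0) * bbox_pad_fraction))
    r0, r1 = max(0, r0 - pr), min(m.shape[1], r1 + pr)
    c0, c1 = max(0, c0 - pc), min(m.shape[2], c1 + pc)

    chosen = _span_indices(first, last, n_slices)
    pairs: list[SlicePair] = []
    for k, z in enumerate(chosen):
        sl_mask = m[z, r0:r1, c0:c1]
        chans = []
        mask_rs = resize(sl_mask.astype(float), (out_size, out_size), order=0,
                         preserve_range=True, anti_aliasing=False) > 0.5
        for vol in (t2, dwi):
            img = np.asarray(vol.grid[z, r0:r1, c0:c1], dtype=np.float64) * sl_mask
            img_rs = resize(img, (out_size, out_size), order=1,
                            preserve_range=True, anti_aliasing=False)
            img_rs[~mask_rs] = 0.0
            chans.append(img_rs)
        pairs.append(SlicePair(np.stack(chans, axis=-1), axial_index=k, region=region))
    while len(pairs) < n_slices:
        pairs.append(SlicePair(np.zeros((out_size, out_size, 2), dtype=np.float32),
                               axial_index=len(pairs), region=region, is_padding=True))
    return pairs


# ---------------------------------------------------------------------------
# clinical encoding


@dataclass
class ClinicalStats:
    """Per-field min/max fitted on the training split only."""

    minima: dict[str, float]
    maxima: dict[str, float]


def fit_clinical_stats(records: list[ClinicalRecord], schema: ClinicalSchema) -> ClinicalStats:
    if not records:
        raise ValueError("cannot fit clinical statistics on an empty split")
    minima, maxima = {}, {}
    for f in schema.numeric_fields:
        vals = [r.numeric[f] for r in records]
        minima[f], maxima[f] = float(min(vals)), float(max(vals))
        if minima[f] == maxima[f]:
            raise ValueError(f"degenerate clinical field '{f}': min == max == {minima[f]}")
    return ClinicalStats(minima=minima, maxima=maxima)


def encode_clinical(record: ClinicalRecord, schema: ClinicalSchema,
                    stats: ClinicalStats) -> ClinicalVector:
    values, names = [], []
    for f in schema.numeric_fields:
        lo, hi = stats.minima[f], stats.maxima[f]
        values.append(float(np.clip((record.numeric[f] - lo) / (hi - lo), 0.0, 1.0)))
        names.append(f)
    for f, codes in schema.categorical_fields.items():
        k = len(codes)
        code = record.categorical[f]
        values.append(0.0 if k == 1 else (code - codes[0]) / (k - 1))
        names.append(f)
    return ClinicalVector(np.array(values), names)


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentParams:
    rotation_deg: float = 10.0
    flip_prob: float = 0.5
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    contrast_range: tuple[float, float] = (0.9, 1.1)


def augment(sp: SlicePair, rng: np.random.Generator,
            params: AugmentParams | None = None) -> SlicePair:
    """Random rotation/flip plus brightness/contrast jitter.

    The same geometric transform is applied to both channels.  Intensity
    jitter acts on foreground (region) pixels only — brightness is an
    additive shift, contrast a multiplicative gain about the foreground
    mean — so background zeros stay exactly zero.  Padding slices pass
    through untouched.
    """
    if sp.is_padding:
        return sp
    params = params or AugmentParams()
    px = sp.pixels.astype(np.float64)
    angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
    do_flip = rng.random() < params.flip_prob
    gain = rng.uniform(*params.contrast_range)
    shift = rng.uniform(*params.brightness_range)

    fg = px.any(axis=-1)
    if angle != 0.0:
        px = ndimage.rotate(px, angle, axes=(1, 0), reshape=False, order=1, cval=0.0)
        fg = ndimage.rotate(fg.astype(np.float32), angle, axes=(1, 0), reshape=False,
                            order=0, cval=0.0) > 0.5
        px[~fg] = 0.0
    if do_flip:
        px = px[:, ::-1, :].copy()
        fg = fg[:, ::-1].copy()
    if fg.any():
        for c in range(2):
            chan = px[..., c]
            mu = chan[fg].mean()
            chan[fg] = gain * (chan[fg] - mu) + mu + shift
    return SlicePair(px, axial_index=sp.axial_index, region=sp.region,
                     is_padding=False)
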