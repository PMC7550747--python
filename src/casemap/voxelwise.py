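"""Whole-brain single-case comparison on registered gray-matter images.

The subject image and the control image stack (all co-registered and
modulated upstream; this module never resamples) are smoothed with the same
Gaussian kernel, an analysis mask is derived from the controls, and the
Crawford-Howell t is evaluated independently at every masked voxel with
n = number of controls and df = n - 1. Atrophy maps use the one-tailed
"less" alternative (gray-matter decrease) and are binarized at an
uncorrected p threshold (default 0.005, strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io_formats import VolumeImage, check_same_grid

#: FWHM = FWHM_TO_SIGMA * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

DEFAULT_GM_FLOOR = 0.1
DEFAULT_SD_FLOOR = 1e-6
DEFAULT_P_THRESHOLD = 0.005
DEFAULT_FWHM_MM = 8.0


@dataclass
class StatMap:
    """Voxelwise t and p images with their shared analysis mask."""

    t: VolumeImage
    p: VolumeImage
    df: int
    mask: VolumeImage
    tails: str


@dataclass
class BinaryMap:
    """Thresholded, binarized atrophy map (values exactly 0/1)."""

    data: VolumeImage
    threshold_p: float
    direction: str

    @property
    def count(self) -> int:
        return int(self.data.data.sum())


def gaussian_smooth(img: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Per-axis Gaussian smoothing specified as FWHM in millimetres.

    sigma per axis = fwhm / (2*sqrt(2*ln 2)) / voxel_size_axis, so anisotropic
    voxels get anisotropic kernels. fwhm 0 is the identity. Wraparound
    boundary handling keeps the total image sum exactly conserved; images are
    expected to be zero at the grid boundary.
    """
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return img.like(img.data.copy())
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / img.voxel_size
    return img.like(ndimage.gaussian_filter(img.data.astype(float), sigma=sigma_vox, mode="wrap"))


def compute_analysis_mask(
    control_imgs: list[VolumeImage],
    gm_floor: float = DEFAULT_GM_FLOOR,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> VolumeImage:
    """Voxels eligible for testing: enough mean control GM and non-degenerate SD."""
    if len(control_imgs) < 2:
        raise ValueError("need at least 2 control images to build an analysis mask")
    check_same_grid(control_imgs)
    stack = np.stack([c.data for c in control_imgs])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    mask = (mean >= gm_floor) & (sd >= sd_floor)
    return control_imgs[0].like(mask.astype(np.uint8))


def voxelwise_single_case(
    subject_img: VolumeImage,
    control_imgs: list[VolumeImage],
    tails: str = "less",
    fwhm_mm: float = DEFAULT_FWHM_MM,
    gm_floor: float = DEFAULT_GM_FLOOR,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> StatMap:
    """Per-voxel Crawford-Howell comparison of one subject vs the control stack.

    Subject and controls are smoothed with the same kernel before testing
    (unequal smoothing would break exchangeability). Outside the analysis
    mask, t and p are NaN.
    """
    check_same_grid([subject_img, *control_imgs])
    if len(control_imgs) < 2:
        raise ValueError("need at least 2 control images")
    if tails not in ("two", "less", "greater"):
        raise ValueError(f"tails must be two|less|greater, got {tails!r}")

    subject = gaussian_smooth(subject_img, fwhm_mm)
    controls = [gaussian_smooth(c, fwhm_mm) for c in control_imgs]

    mask_img = compute_analysis_mask(controls, gm_floor=gm_floor, sd_floor=sd_floor)
    mask = mask_img.data.astype(bool)

    stack = np.stack([c.data for c in controls])
    n = stack.shape[0]
    df = n - 1
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)

    t = np.full(subject.shape, np.nan)
    p = np.full(subject.shape, np.nan)
    denom = sd[mask] * math.sqrt((n + 1) / n)
    t_in = (subject.data[mask] - mean[mask]) / denom
    if tails == "two":
        p_in = 2.0 * stats.t.sf(np.abs(t_in), df)
    elif tails == "less":
        p_in = stats.t.cdf(t_in, df)
    else:
        p_in = stats.t.sf(t_in, df)
    t[mask] = t_in
    p[mask] = np.minimum(p_in, 1.0)

    return StatMap(
        t=subject.like(t), p=subject.like(p), df=df, mask=mask_img, tails=tails
    )


def threshold_binarize(stat: StatMap, p_threshold: float = DEFAULT_P_THRESHOLD) -> BinaryMap:
    """Binarize a stat map at an uncorrected voxel p threshold (strict <).

    With one-tailed maps the p-value already encodes the direction; with
    two-tailed maps, only voxels below the control mean (t < 0, atrophy) are
    kept, matching the decrease-only aggregation downstream.
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p threshold must be in (0, 1), got {p_threshold}")
    mask = stat.mask.data.astype(bool)
    hit = np.zeros(stat.p.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        hit[mask] = stat.p.data[mask] < p_threshold
        if stat.tails == "two":
            hit &= stat.t.data < 0
    direction = {"two": "below", "less": "below", "greater": "above"}[stat.tails]
    return BinaryMap(
        data=stat.p.like(hit.astype(np.uint8)),
        threshold_p=p_threshold,
        direction=direction,
    )
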