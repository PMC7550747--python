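"""Aggregation of per-subject binary atrophy maps across a patient group.

Binary neurodegeneration patterns are summed and normalized into a
probability overlap map (voxel value = fraction of subjects atrophic there),
consensus maps are cut at a fraction threshold (75% / 90% conventions,
inclusive), and region masks yield atrophy prevalence percentages and
affected-voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import VolumeImage, check_same_grid
from .voxelwise import BinaryMap


@dataclass
class OverlapMap:
    """Voxelwise fraction of subjects whose binary map includes the voxel."""

    probability: VolumeImage
    n_subjects: int
    contributing_ids: list[str] = field(default_factory=list)


@dataclass
class RegionMask:
    """Named binary region-of-interest mask."""

    name: str
    data: VolumeImage

    def __post_init__(self) -> None:
        vals = np.unique(self.data.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask {self.name!r} has non-binary values")

    @property
    def voxel_count(self) -> int:
        return int(self.data.data.sum())


def union_mask(*masks: RegionMask, name: str | None = None) -> RegionMask:
    """Voxelwise union of masks (e.g. 'either caudate or putamen')."""
    check_same_grid([m.data for m in masks])
    combined = np.zeros(masks[0].data.shape, dtype=np.uint8)
    for m in masks:
        combined |= m.data.data.astype(np.uint8)
    return RegionMask(
        name=name or "|".join(m.name for m in masks),
        data=masks[0].data.like(combined),
    )


def overlap_probability_map(
    binaries: list[BinaryMap], subject_ids: list[str] | None = None
) -> OverlapMap:
    """Sum the binary maps and normalize by the number of subjects."""
    if not binaries:
        raise ValueError("need at least one binary map")
    imgs = [b.data for b in binaries]
    check_same_grid(imgs)
    total = np.sum([img.data for img in imgs], axis=0, dtype=float)
    n = len(binaries)
    return OverlapMap(
        probability=imgs[0].like(total / n),
        n_subjects=n,
        contributing_ids=list(subject_ids or []),
    )


def threshold_overlap(overlap: OverlapMap, fraction: float) -> BinaryMap:
    """Consensus map: voxels atrophic in at least ``fraction`` of subjects (inclusive)."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    hit = overlap.probability.data >= fraction
    return BinaryMap(
        data=overlap.probability.like(hit.astype(np.uint8)),
        threshold_p=fraction,
        direction="below",
    )


def affected_voxel_count(binary: BinaryMap, mask: RegionMask | None = None) -> int:
    """Number of atrophic voxels, optionally restricted to a region mask."""
    data = binary.data.data
    if mask is not None:
        check_same_grid([binary.data, mask.data])
        data = data * mask.data.data
    return int(data.sum())


def region_atrophy_prevalence(
    binaries: list[BinaryMap], mask: RegionMask, min_voxels: int = 1
) -> tuple[int, float]:
    """Count and percentage of subjects atrophic within a region.

    A subject counts as atrophic when at least ``min_voxels`` of its binary
    map fall inside the mask. Pass a union mask for either-of-two-regions
    prevalence.
    """
    if mask.voxel_count == 0:
        raise ValueError(f"region mask {mask.name!r} is empty")
    if not binaries:
        raise ValueError("need at least one binary map")
    check_same_grid([mask.data, *(b.data for b in binaries)])
    count = sum(
        1 for b in binaries if affected_voxel_count(b, mask) >= min_voxels
    )
    return count, 100.0 * count / len(binaries)
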