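"""Group probability overlap map from per-patient binary atrophy maps.

Eight synthetic patients share a lesion in the 'caudate' sphere; half also
have a second lesion. Per-patient voxelwise comparisons are binarized and
aggregated into a probability overlap map, consensus maps at 75% and 90%,
and region atrophy prevalence.
"""

from casemap import (
    RegionMask,
    SimulationConfig,
    overlap_probability_map,
    region_atrophy_prevalence,
    simulate_gm_images,
    threshold_binarize,
    threshold_overlap,
    voxelwise_single_case,
)
from casemap.io_formats import VolumeImage
from casemap.synthetic import sphere_mask

import numpy as np

shared, private = (16, 16, 16), (10, 10, 10)
implants = []
for i in range(8):
    implants.append((f"pat{i:03d}", shared, 4.0, 5.0))
    if i % 2 == 0:
        implants.append((f"pat{i:03d}", private, 3.0, 5.0))

config = SimulationConfig(
    seed=3, n_controls=20, n_patients=8, grid_shape=(32, 32, 32),
    image_noise_sd=0.05, implants_voxel=implants,
)
images = simulate_gm_images(config)
controls = [images[f"ctrl{i:03d}"] for i in range(20)]

binaries = []
for i in range(8):
    stat = voxelwise_single_case(images[f"pat{i:03d}"], controls, fwhm_mm=4.0)
    binaries.append(threshold_binarize(stat, 0.005))

overlap = overlap_probability_map(binaries)
consensus75 = threshold_overlap(overlap, 0.75)
consensus90 = threshold_overlap(overlap, 0.90)

affine = np.diag([2.0, 2.0, 2.0, 1.0])
region = RegionMask("shared-lesion-site", VolumeImage(
    data=sphere_mask((32, 32, 32), shared, 4.0).astype(float), affine=affine))
count, percent = region_atrophy_prevalence(binaries, region)

print(f"probability at the shared lesion center: "
      f"{overlap.probability.data[shared]:.2f}")
print(f"voxels atrophic in >= 75% of patients: {consensus75.count}")
print(f"voxels atrophic in >= 90% of patients: {consensus90.count}")
print(f"patients with atrophy inside the region mask: {count}/8 ({percent:.2f}%)")
print("\nThe consensus maps isolate voxels consistently atrophic across the")
print("group; prevalence counts patients with any suprathreshold voxel there.")
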