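"""Whole-brain single-case comparison with an implanted focal lesion.

Simulates 20 co-registered control gray-matter images and one patient with a
sphere of atrophy (radius 5 voxels, 4 noise-SDs deep), smooths everything
with a 4 mm kernel, computes the per-voxel Crawford-Howell t-map, and
binarizes at uncorrected p < 0.005.
"""

import numpy as np

from casemap import SimulationConfig, simulate_gm_images, threshold_binarize, voxelwise_single_case
from casemap.synthetic import sphere_mask

center, radius = (16, 16, 16), 5.0
config = SimulationConfig(
    seed=11, n_controls=20, n_patients=1, grid_shape=(32, 32, 32),
    image_noise_sd=0.05,
    implants_voxel=[("pat000", center, radius, 4.0)],
)
images = simulate_gm_images(config)
controls = [images[f"ctrl{i:03d}"] for i in range(20)]

stat = voxelwise_single_case(images["pat000"], controls, tails="less", fwhm_mm=4.0)
binary = threshold_binarize(stat, p_threshold=0.005)

truth = sphere_mask((32, 32, 32), center, radius)
detected = binary.data.data.astype(bool)
dice = 2 * np.logical_and(detected, truth).sum() / (detected.sum() + truth.sum())
peak = np.unravel_index(np.nanargmin(stat.t.data), stat.t.data.shape)

print(f"analysis mask: {int(stat.mask.data.sum())} voxels, df = {stat.df}")
print(f"suprathreshold voxels (p < 0.005, GM decrease): {binary.count}")
print(f"peak t = {np.nanmin(stat.t.data):.2f} at voxel {peak}")
print(f"Dice overlap with the implanted sphere: {dice:.2f}")
print("\nThe detected cluster should coincide with the implanted sphere; the")
print("Dice coefficient quantifies that spatial agreement (1 = perfect).")
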