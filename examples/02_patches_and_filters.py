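"""Patch-grid extraction, lung coverage, the healthy filter and subsampling.

The grid spans the lung bounding box; patches keeping at least half their
voxels inside the lung are retained, and the union of retained patches
should cover > 70% of the lung. The healthy filter keeps only patches with
strictly less than 1% emphysema, which is how the "normal-appearing"
training pool for the density model is built.
"""

import lungood as lg

pair = lg.generate_phantom(
    lg.PhantomSpec(emphysema_burden=0.10, seed=3), subject_id="demo")
grid = lg.PatchGridSpec(patch_edge=16, overlap_fraction=0.2)

patches, report = lg.extract_patch_grid(pair, grid)
print(f"{len(patches)} patches, lung coverage {report.coverage:.1%} "
      f"(target {report.coverage_target:.0%}, flagged: {report.below_target})")

healthy = lg.filter_healthy_patches(patches)
print(f"healthy filter: {len(healthy)}/{len(patches)} patches keep "
      "< 1% in-lung voxels below -950 HU")

capped = lg.subsample_patches(patches, max_n=10, seed=0)
print(f"subsampled to {len(capped)} patches (seed-deterministic cap)")

norm = lg.normalize_intensities(patches[0])
print(f"normalized intensity range: [{norm.data.min():.3f}, "
      f"{norm.data.max():.3f}] (HU window [-1024, 100] mapped to [0, 1])")
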