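"""Build and render a volumetric anomaly map for one diseased phantom.

Patch scores are mean-accumulated into the CT geometry, min-max normalized
by the 5th/95th percentiles of all patch scores, and overlaid in red on
the CT windowed to [-1300, 50] HU.
"""

from pathlib import Path

import numpy as np

import lungood as lg
from lungood.density import select_k_bic

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

controls = lg.generate_cohort(8, 0, (0, 0), seed=21)
sick = lg.generate_phantom(
    lg.PhantomSpec(emphysema_burden=0.15, airtrap_burden=0.15, seed=77),
    subject_id="sick")
grid = lg.PatchGridSpec(patch_edge=16, overlap_fraction=0.2)

ctrl_patches = [p for pair in controls
                for p in lg.filter_healthy_patches(
                    lg.extract_patch_grid(pair, grid)[0])]
sick_patches = lg.extract_patch_grid(sick, grid)[0]
enc = lg.train_encoder(ctrl_patches + sick_patches,
                       lg.EncoderConfig(epochs=3, batch_size=32, seed=0))
gmm = select_k_bic(np.stack([r.z for r in lg.encode(enc, ctrl_patches)]),
                   seed=0)

scores = lg.score_representations(gmm, lg.encode(enc, sick_patches))
reference = [a.s for a in scores] + [
    a.s for a in lg.score_representations(gmm, lg.encode(enc, ctrl_patches))]

amap = lg.build_map(scores, grid, sick.insp.shape)
amap = lg.normalize_map(amap, reference)
png = out_dir / "sick_anomaly_map.png"
lg.render_overlay(sick.insp, amap, slice_axis=1, out_path=png)

inside = np.isfinite(amap.values)
print(f"normalized map range: [{amap.values[inside].min():.2f}, "
      f"{amap.values[inside].max():.2f}] over {inside.sum()} covered voxels")
print(f"normalization percentiles: p5={amap.p5:.1f}, p95={amap.p95:.1f} nats")
print(f"coronal overlay written to {png}")
print("(red regions are patches unlikely under the control density)")
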