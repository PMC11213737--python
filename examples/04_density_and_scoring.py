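"""Fit the control density p(z) and score patches by -log p(z).

The density sees only healthy-filtered control patches. Patches from a
diseased lung should then receive higher anomaly scores, and within a
diseased lung, lesion-covering patches should outscore lesion-free ones.
"""

import numpy as np

import lungood as lg
from lungood.density import select_k_bic

controls = lg.generate_cohort(10, 0, (0, 0), seed=5)
diseased = lg.generate_phantom(
    lg.PhantomSpec(emphysema_burden=0.15, airtrap_burden=0.15, seed=99),
    subject_id="sick")
grid = lg.PatchGridSpec(patch_edge=16, overlap_fraction=0.2)

ctrl_patches = [p for pair in controls
                for p in lg.filter_healthy_patches(
                    lg.extract_patch_grid(pair, grid)[0])]
sick_patches = lg.extract_patch_grid(diseased, grid)[0]

cfg = lg.EncoderConfig(epochs=3, batch_size=32, seed=0)
enc = lg.train_encoder(ctrl_patches + sick_patches, cfg)

Z = np.stack([r.z for r in lg.encode(enc, ctrl_patches)])
gmm = select_k_bic(Z, seed=0)
print(f"BIC chose K={gmm.n_components} mixture components "
      f"on {len(Z)} control representations")

ctrl_scores = [a.s for a in lg.score_representations(
    gmm, lg.encode(enc, ctrl_patches))]
sick_scores = lg.score_representations(gmm, lg.encode(enc, sick_patches))
print(f"median control patch score:  {np.median(ctrl_scores):.1f} nats")
print(f"median diseased patch score: "
      f"{np.median([a.s for a in sick_scores]):.1f} nats")

S = lg.aggregate([a.s for a in sick_scores], "mean", "sick")
print(f"patient-level score S(X) (mean aggregation): {S.S:.1f}")
print("(higher = less likely under the normal-appearing-lung density)")
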