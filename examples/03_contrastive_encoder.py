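"""Train the contrastive patch encoder and inspect what it learned.

Two augmented views of one patch are a positive pair; other patches in the
batch are negatives. After training, representations of lesion-containing
and healthy patches should be farther apart across groups than within.
"""

import numpy as np

import lungood as lg

control = lg.generate_phantom(lg.PhantomSpec(seed=2), subject_id="ctrl")
diseased = lg.generate_phantom(
    lg.PhantomSpec(emphysema_burden=0.15, airtrap_burden=0.15, seed=1),
    subject_id="sick")
grid = lg.PatchGridSpec(patch_edge=16, overlap_fraction=0.2)
patches = (lg.extract_patch_grid(control, grid)[0]
           + lg.extract_patch_grid(diseased, grid)[0])

cfg = lg.EncoderConfig(epochs=4, batch_size=32, seed=0)
enc = lg.train_encoder(patches, cfg)
print(f"NT-Xent loss: {enc.loss_trace[0]:.3f} -> {enc.loss_trace[-1]:.3f} "
      f"over {len(enc.loss_trace)} steps")

healthy = lg.filter_healthy_patches(patches)
lesion = [p for p in patches if id(p) not in {id(h) for h in healthy}]
zh = np.stack([r.z for r in lg.encode(enc, healthy)])
zl = np.stack([r.z for r in lg.encode(enc, lesion)])


def mean_dist(a, b):
    return np.mean(np.linalg.norm(a[:, None] - b[None], axis=-1))


print(f"mean latent distance, healthy vs lesion: {mean_dist(zh, zl):.2f}")
print(f"mean latent distance within groups:      "
      f"{0.5 * (mean_dist(zh, zh) + mean_dist(zl, zl)):.2f}")
print("(a larger across-group distance means lesion content is encoded)")
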