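"""Self-supervised contrastive patch encoder.

Two stochastic augmentations of the same patch form a positive pair; all
other patches in the batch act as negatives. The NT-Xent objective pulls
positive projections together and pushes negatives apart on the unit
hypersphere. Representations used downstream are the backbone output
(pre-projection); the projection head exists only for the loss.

The backbone is a small 3D convolutional network: stride-2 valid
convolutions with ReLU, global average pooling, then a linear map to the
latent space. Three conv blocks are used for patch edges below 32 and four
for larger patches, so the receptive field always collapses to a single
spatial cell before pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .nn.autodiff import Adam, Tensor
from .nn.layers import Conv3d, Linear
from .preproc import normalize_intensities
from .types import PatchSample, Representation

__all__ = [
    "EncoderConfig",
    "TrainedEncoder",
    "augment_pair",
    "ntxent_loss",
    "train_encoder",
    "encode",
    "save_encoder",
    "load_encoder",
]


@dataclass(frozen=True)
class EncoderConfig:
    latent_dim: int = 64
    projection_dim: int = 32
    temperature: float = 0.1
    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    flip_prob: float = 0.5
    max_rotation_deg: float = 10.0
    intensity_jitter_sd: float = 0.02
    crop_rescale_min: float = 0.8
    mask_background: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.latent_dim >= self.projection_dim >= 2:
            raise ValueError("need latent_dim >= projection_dim >= 2")
        if not 0.0 < self.crop_rescale_min <= 1.0:
            raise ValueError("crop_rescale_min must be in (0, 1]")


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _augment_once(data: np.ndarray, cfg: EncoderConfig,
                  rng: np.random.Generator) -> np.ndarray:
    out = data
    # random flips, per spatial axis
    for ax in (1, 2, 3):
        if rng.random() < cfg.flip_prob:
            out = np.flip(out, axis=ax)
    # small rotation in a random spatial plane
    if cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        planes = [(1, 2), (1, 3), (2, 3)]
        axes = planes[rng.integers(len(planes))]
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=axes, reshape=False,
                                 order=1, mode="nearest")
    # random crop then rescale back to the original edge
    if cfg.crop_rescale_min < 1.0:
        e = out.shape[-1]
        ce = int(round(e * rng.uniform(cfg.crop_rescale_min, 1.0)))
        if ce < e:
            corner = [rng.integers(0, e - ce + 1) for _ in range(3)]
            crop = out[:, corner[0]:corner[0] + ce, corner[1]:corner[1] + ce,
                       corner[2]:corner[2] + ce]
            zoom = e / ce
            out = np.stack([
                ndimage.zoom(c, zoom, order=1, mode="nearest", grid_mode=True)
                for c in crop
            ])
            if out.shape[-1] != e:  # rounding guard
                out = out[:, :e, :e, :e]
    # additive intensity jitter
    if cfg.intensity_jitter_sd > 0:
        out = out + rng.normal(0.0, cfg.intensity_jitter_sd, size=out.shape)
    return np.ascontiguousarray(out, dtype=np.float64)


def augment_pair(patch: PatchSample, cfg: EncoderConfig, seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Two stochastic views of one normalized patch; deterministic per seed.

    With all augmentation strengths at zero both views equal the patch.
    """
    patch = normalize_intensities(patch)
    rng = np.random.default_rng(seed)
    return (_augment_once(patch.data, cfg, rng),
            _augment_once(patch.data, cfg, rng))


# ---------------------------------------------------------------------------
# NT-Xent loss
# ---------------------------------------------------------------------------

def _ntxent_graph(proj: Tensor, temperature: float) -> Tensor:
    """NT-Xent on a (2B, P) projection matrix; rows 2k and 2k+1 are a pair."""
    n = proj.shape[0]
    if n % 2 != 0 or n < 2:
        raise ValueError("projections must stack an even number >= 2 of rows")
    norms_sq = (proj * proj).sum(axis=1, keepdims=True)
    if np.any(norms_sq.data <= 0):
        raise ValueError("zero-vector projection row: cosine similarity undefined")
    xn = proj / norms_sq.sqrt()
    sim = (xn @ xn.T) * (1.0 / temperature)

    off_diag = 1.0 - np.eye(n)
    # rowwise max over the off-diagonal, detached, for a stable softmax
    m = np.max(np.where(off_diag > 0, sim.data, -np.inf), axis=1, keepdims=True)
    expo = (sim - m).exp() * off_diag
    denom = expo.sum(axis=1)

    partner = np.arange(n) ^ 1
    pos = sim.take_flat(np.arange(n) * n + partner)
    losses = denom.log() + Tensor(m.reshape(-1)) - pos
    return losses.mean()


def ntxent_loss(projections: np.ndarray, temperature: float = 0.1) -> float:
    """Normalized-temperature cross-entropy over cosine similarities.

    Mean over all 2B anchors of -log of the softmax probability assigned to
    the anchor's positive among all other rows (self excluded). With a
    single pair (B = 1) the denominator holds the positive only and the
    loss is 0.
    """
    return float(_ntxent_graph(Tensor(np.asarray(projections, float)),
                               temperature).data)


# ---------------------------------------------------------------------------
# encoder network
# ---------------------------------------------------------------------------

class _Backbone:
    def __init__(self, n_channels: int, edge: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        n_blocks = 4 if edge >= 32 else 3
        widths = [n_channels] + [8 * 2**i for i in range(n_blocks)]
        self.convs = [
            Conv3d(widths[i], widths[i + 1], k=3, stride=2, rng=rng)
            for i in range(n_blocks)
        ]
        self.fc = Linear(widths[-1], cfg.latent_dim, rng)
        self.head1 = Linear(cfg.latent_dim, cfg.latent_dim, rng)
        self.head2 = Linear(cfg.latent_dim, cfg.projection_dim, rng)
        self.n_channels = n_channels
        self.edge = edge

    def features(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        # global average pool over remaining spatial cells
        n, c = x.shape[0], x.shape[1]
        return x.reshape(n, c, -1).mean(axis=2)

    def latent(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))

    def project(self, z: Tensor) -> Tensor:
        return self.head2(self.head1(z).relu())

    @property
    def params(self):
        ps = [p for c in self.convs for p in c.params]
        return ps + self.fc.params + self.head1.params + self.head2.params


@dataclass
class TrainedEncoder:
    """Frozen contrastive encoder plus its training-loss trace."""

    config: EncoderConfig
    backbone: _Backbone
    loss_trace: list[float]

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def _prepare(patch: PatchSample, cfg: EncoderConfig) -> PatchSample:
    """Normalize and, by default, zero out non-lung voxels.

    Background soft tissue is far brighter than parenchyma and dominates
    the variance of boundary patches; masking it focuses the
    representation on lung content.
    """
    out = normalize_intensities(patch)
    if cfg.mask_background and patch.lung_mask is not None:
        out = PatchSample(data=out.data * patch.lung_mask[None],
                          origin=out.origin, lung_fraction=out.lung_fraction,
                          subject_id=out.subject_id, lung_mask=out.lung_mask,
                          normalized=True)
    return out


def _as_batch(patches: list[PatchSample], cfg: EncoderConfig) -> np.ndarray:
    return np.stack([_prepare(p, cfg).data for p in patches])


def train_encoder(patches: list[PatchSample], cfg: EncoderConfig
                  ) -> TrainedEncoder:
    """Train the contrastive encoder on patches; deterministic given the seed.

    Patches in HU are normalized on entry. Raises on fewer than two patches,
    inconsistent channel counts, or a NaN loss.
    """
    if len(patches) < 2:
        raise ValueError("contrastive training needs at least 2 patches")
    n_ch = {p.n_channels for p in patches}
    edges = {p.edge for p in patches}
    if len(n_ch) != 1 or len(edges) != 1:
        raise ValueError(
            f"inconsistent patch geometry: channels {n_ch}, edges {edges}"
        )
    patches = [_prepare(p, cfg) for p in patches]

    ss = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    aug_seeds = iter(np.random.SeedSequence(cfg.seed + 1).generate_state(
        cfg.epochs * max(len(patches), cfg.batch_size) * 4).tolist())

    backbone = _Backbone(n_ch.pop(), edges.pop(), cfg, init_rng)
    opt = Adam(backbone.params, lr=cfg.learning_rate)
    trace: list[float] = []

    for _ in range(cfg.epochs):
        idx = order_rng.permutation(len(patches))
        for start in range(0, len(idx), cfg.batch_size):
            batch = [patches[i] for i in idx[start:start + cfg.batch_size]]
            if len(batch) < 2:
                continue
            views = []
            for p in batch:
                a, b = augment_pair(p, cfg, seed=next(aug_seeds))
                views.extend([a, b])
            x = Tensor(np.stack(views))
            proj = backbone.project(backbone.latent(x))
            loss = _ntxent_graph(proj, cfg.temperature)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf NT-Xent loss at step {len(trace)} "
                    f"(lr={cfg.learning_rate}, temperature={cfg.temperature})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
    return TrainedEncoder(config=cfg, backbone=backbone, loss_trace=trace)


def encode(encoder: TrainedEncoder, patches: list[PatchSample],
           batch_size: int = 64) -> list[Representation]:
    """Map patches to latent representations z = f(x); no weight updates."""
    if not patches:
        return []
    if any(p.n_channels != encoder.backbone.n_channels for p in patches):
        raise ValueError("patch channel count does not match the encoder")
    reps: list[Representation] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        z = encoder.backbone.latent(
            Tensor(_as_batch(chunk, encoder.config))).data
        for p, zi in zip(chunk, z):
            reps.append(Representation(z=zi.copy(), subject_id=p.subject_id,
                                       origin=p.origin))
    return reps


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_encoder(encoder: TrainedEncoder, path) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(encoder.backbone.params)}
    meta = dict(asdict(encoder.config),
                n_channels=encoder.backbone.n_channels,
                edge=encoder.backbone.edge)
    np.savez(path, __meta__=json.dumps(meta),
             __trace__=np.asarray(encoder.loss_trace), **arrays)


def load_encoder(path) -> TrainedEncoder:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        trace = f["__trace__"].tolist()
        n_channels = meta.pop("n_channels")
        edge = meta.pop("edge")
        cfg = EncoderConfig(**meta)
        backbone = _Backbone(n_channels, edge, cfg, np.random.default_rng(0))
        for i, p in enumerate(backbone.params):
            p.data = f[f"p{i}"].astype(np.float64)
    return TrainedEncoder(config=cfg, backbone=backbone, loss_trace=trace)
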