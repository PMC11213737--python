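"""Contrastive encoder: augmentations, NT-Xent oracle checks, training."""

import numpy as np
import pytest

import lungood as lg
from lungood.encoder import augment_pair, save_encoder, load_encoder
from lungood.types import PatchSample


def _norm_patch(seed=0, edge=8, channels=1):
    rng = np.random.default_rng(seed)
    return PatchSample(data=rng.random((channels, edge, edge, edge)),
                       origin=(0, 0, 0), lung_fraction=1.0, subject_id="t",
                       normalized=True)


_NO_AUG = dict(flip_prob=0.0, max_rotation_deg=0.0, intensity_jitter_sd=0.0,
               crop_rescale_min=1.0)


def test_augment_identity_limit():
    patch = _norm_patch()
    cfg = lg.EncoderConfig(**_NO_AUG)
    a, b = augment_pair(patch, cfg, seed=3)
    np.testing.assert_array_equal(a, patch.data)
    np.testing.assert_array_equal(b, patch.data)


def test_augment_deterministic_per_seed():
    patch = _norm_patch(1)
    cfg = lg.EncoderConfig()
    a1, b1 = augment_pair(patch, cfg, seed=7)
    a2, b2 = augment_pair(patch, cfg, seed=7)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(b1, b2)
    a3, _ = augment_pair(patch, cfg, seed=8)
    assert not np.array_equal(a1, a3)


def test_flip_only_augmentation_preserves_voxel_multiset():
    patch = _norm_patch(2)
    cfg = lg.EncoderConfig(**{**_NO_AUG, "flip_prob": 1.0})
    a, b = augment_pair(patch, cfg, seed=0)
    np.testing.assert_allclose(np.sort(a.reshape(-1)),
                               np.sort(patch.data.reshape(-1)))
    np.testing.assert_allclose(np.sort(b.reshape(-1)),
                               np.sort(patch.data.reshape(-1)))


# --- NT-Xent ---------------------------------------------------------------

def _brute_ntxent(X, tau):
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    S = Xn @ Xn.T / tau
    n = len(X)
    total = 0.0
    for i in range(n):
        j = i ^ 1
        denom = sum(np.exp(S[i, k]) for k in range(n) if k != i)
        total += -np.log(np.exp(S[i, j]) / denom)
    return total / n


def test_ntxent_hand_computed_two_pair_batch():
    """Identical positives, orthogonal cross-pairs, tau=1: -log(e/(e+2))."""
    P = np.array([[1.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]])
    expected = -np.log(np.e / (np.e + 2.0))
    assert lg.ntxent_loss(P, 1.0) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("b", [2, 3, 4, 6])
def test_ntxent_matches_brute_force(b, rng):
    X = rng.normal(size=(2 * b, 5))
    assert lg.ntxent_loss(X, 0.37) == pytest.approx(_brute_ntxent(X, 0.37),
                                                    abs=1e-6)


def test_ntxent_uniform_softmax_limit(rng):
    """At huge temperature all similarities flatten: loss -> log(2B-1)."""
    X = rng.normal(size=(8, 4))
    assert lg.ntxent_loss(X, 1e6) == pytest.approx(np.log(7), abs=1e-3)


def test_ntxent_pair_block_permutation_invariance(rng):
    X = rng.normal(size=(8, 4))
    perm = np.array([4, 5, 0, 1, 6, 7, 2, 3])  # permute pairs, keep partners
    assert lg.ntxent_loss(X, 0.2) == pytest.approx(
        lg.ntxent_loss(X[perm], 0.2), abs=1e-10)


def test_ntxent_single_pair_is_zero():
    assert lg.ntxent_loss(np.array([[1.0, 0], [0.3, 0.4]]), 0.5) == 0.0


def test_ntxent_zero_row_rejected():
    with pytest.raises(ValueError, match="zero"):
        lg.ntxent_loss(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]), 0.5)


# --- training & encoding ---------------------------------------------------

def test_training_reduces_smoothed_loss(trained_encoder):
    trace = np.asarray(trained_encoder.loss_trace)
    k = max(len(trace) // 5, 1)
    assert trace[-k:].mean() < trace[:k].mean()


def test_training_is_seed_deterministic(small_patch_set):
    cfg = lg.EncoderConfig(epochs=1, batch_size=16, seed=9)
    a = lg.train_encoder(small_patch_set[:32], cfg)
    b = lg.train_encoder(small_patch_set[:32], cfg)
    assert a.loss_trace == pytest.approx(b.loss_trace, abs=1e-12)


def test_training_preconditions(small_patch_set):
    with pytest.raises(ValueError, match="at least 2"):
        lg.train_encoder(small_patch_set[:1], lg.EncoderConfig())
    mixed = [small_patch_set[0],
             PatchSample(data=np.zeros((1, 16, 16, 16)), origin=(0, 0, 0),
                         lung_fraction=1.0, subject_id="x", normalized=True)]
    with pytest.raises(ValueError, match="channel"):
        lg.train_encoder(mixed, lg.EncoderConfig())


def test_encode_identical_patches_identical_z(trained_encoder, small_patch_set):
    reps = lg.encode(trained_encoder, [small_patch_set[0], small_patch_set[0]])
    np.testing.assert_array_equal(reps[0].z, reps[1].z)
    assert reps[0].z.shape == (trained_encoder.latent_dim,)


def test_encode_batched_equals_sequential(trained_encoder, small_patch_set):
    subset = small_patch_set[:10]
    batched = lg.encode(trained_encoder, subset, batch_size=8)
    single = [lg.encode(trained_encoder, [p])[0] for p in subset]
    for b, s in zip(batched, single):
        np.testing.assert_allclose(b.z, s.z, atol=1e-5)


def test_representations_separate_lesion_content(trained_encoder,
                                                 small_patch_set):
    """Lesion-rich and healthy patches are farther apart across groups
    than within groups after contrastive training."""
    healthy = lg.filter_healthy_patches(small_patch_set)
    lesion = [p for p in small_patch_set
              if id(p) not in {id(h) for h in healthy}]
    assert healthy and lesion
    zh = np.stack([r.z for r in lg.encode(trained_encoder, healthy)])
    zl = np.stack([r.z for r in lg.encode(trained_encoder, lesion)])

    def mean_pdist(A, B):
        return np.mean(np.linalg.norm(A[:, None] - B[None], axis=-1))

    across = mean_pdist(zh, zl)
    within = 0.5 * (mean_pdist(zh, zh) + mean_pdist(zl, zl))
    assert across > within


def test_checkpoint_roundtrip(tmp_path, trained_encoder, small_patch_set):
    path = tmp_path / "enc.npz"
    save_encoder(trained_encoder, path)
    loaded = load_encoder(path)
    a = lg.encode(trained_encoder, small_patch_set[:4])
    b = lg.encode(loaded, small_patch_set[:4])
    for x, y in zip(a, b):
        np.testing.assert_allclose(x.z, y.z, atol=1e-12)
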