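"""Patch grid, coverage accounting, healthy filter, subsampling, normalization."""

import numpy as np
import pytest

import lungood as lg
from lungood.types import CTVolumePair, PatchSample


def _pair_with_mask(mask, fill=-850.0):
    shape = mask.shape
    insp = np.full(shape, fill)
    exp = np.full(shape, -750.0)
    return CTVolumePair(insp=insp, exp_registered=exp, lung_mask=mask,
                        spacing=(1, 1, 1), subject_id="t")


def _brute_union_coverage(patches, edge, mask):
    covered = np.zeros(mask.shape, dtype=bool)
    for p in patches:
        oz, oy, ox = p.origin
        covered[oz:oz + edge, oy:oy + edge, ox:ox + edge] = True
    return np.logical_and(covered, mask).sum() / mask.sum()


def test_full_volume_grid_no_overlap():
    mask = np.ones((100, 100, 100), dtype=np.uint8)
    pair = _pair_with_mask(mask)
    grid = lg.PatchGridSpec(patch_edge=50, overlap_fraction=0.0,
                            min_lung_fraction=0.5)
    patches, report = lg.extract_patch_grid(pair, grid)
    assert {p.origin for p in patches} == {
        (a, b, c) for a in (0, 50) for b in (0, 50) for c in (0, 50)
    }
    assert report.coverage == pytest.approx(1.0)
    assert not report.below_target


def test_overlap_grid_stride_and_coverage_monotonicity():
    mask = np.ones((100, 100, 100), dtype=np.uint8)
    pair = _pair_with_mask(mask)
    g0 = lg.PatchGridSpec(patch_edge=50, overlap_fraction=0.0)
    g20 = lg.PatchGridSpec(patch_edge=50, overlap_fraction=0.2)
    assert g20.stride == 40
    p0, r0 = lg.extract_patch_grid(pair, g0)
    p20, r20 = lg.extract_patch_grid(pair, g20)
    origins = sorted({p.origin[0] for p in p20})
    assert origins == [0, 40, 50]  # 80 clamped to 50 so the patch fits
    assert r20.coverage >= r0.coverage


@pytest.mark.parametrize("overlap", [0.0, 0.2])
def test_coverage_matches_brute_force_union(overlap, control_pair, grid16):
    grid = lg.PatchGridSpec(patch_edge=16, overlap_fraction=overlap)
    patches, report = lg.extract_patch_grid(control_pair, grid)
    brute = _brute_union_coverage(patches, 16, control_pair.lung_mask)
    assert report.coverage == pytest.approx(brute, abs=0)


def test_empty_mask_yields_no_patches():
    mask = np.zeros((64, 64, 64), dtype=np.uint8)
    pair = _pair_with_mask(mask)
    with pytest.warns(UserWarning, match="empty lung mask"):
        patches, report = lg.extract_patch_grid(pair, lg.PatchGridSpec(patch_edge=16))
    assert patches == []
    assert report.coverage == 0.0
    assert report.below_target


def test_patch_edge_larger_than_volume_rejected(control_pair):
    with pytest.raises(ValueError, match="patch edge"):
        lg.extract_patch_grid(control_pair, lg.PatchGridSpec(patch_edge=65))


def test_two_channel_patches_are_voxel_aligned(diseased_pair, grid16):
    patches, _ = lg.extract_patch_grid(diseased_pair, grid16)
    p = patches[0]
    oz, oy, ox = p.origin
    sl = (slice(oz, oz + 16), slice(oy, oy + 16), slice(ox, ox + 16))
    np.testing.assert_array_equal(p.data[0], diseased_pair.insp[sl])
    np.testing.assert_array_equal(p.data[1], diseased_pair.exp_registered[sl])
    assert 0.0 <= p.lung_fraction <= 1.0


def _patch_with_lesion_fraction(frac, edge=10):
    """Fully-in-lung patch with an exact fraction of voxels at -1000 HU."""
    data = np.full((1, edge, edge, edge), -850.0)
    n = int(round(frac * edge**3))
    data[0].reshape(-1)[:n] = -1000.0
    return PatchSample(data=data, origin=(0, 0, 0), lung_fraction=1.0,
                       subject_id="t", lung_mask=np.ones((edge,) * 3, bool))


@pytest.mark.parametrize("frac,kept", [(0.0, True), (0.005, True),
                                       (0.01, False), (0.05, False)])
def test_healthy_filter_boundary_is_strict(frac, kept):
    """Exactly 1% emphysema is excluded: the criterion is strictly below 1%."""
    patches = [_patch_with_lesion_fraction(frac)]
    out = lg.filter_healthy_patches(patches)
    assert (len(out) == 1) == kept


def test_healthy_filter_counts_only_in_lung_voxels():
    p = _patch_with_lesion_fraction(0.0)
    # 8 lesion voxels outside the lung mask must not count
    p.lung_mask[:2, :2, :2] = False
    p.data[0, :2, :2, :2] = -1000.0
    assert len(lg.filter_healthy_patches([p])) == 1


def test_healthy_filter_idempotent_and_order_preserving(small_patch_set):
    once = lg.filter_healthy_patches(small_patch_set)
    twice = lg.filter_healthy_patches(once)
    assert [id(p) for p in once] == [id(p) for p in twice]
    pos = {id(p): i for i, p in enumerate(small_patch_set)}
    assert [pos[id(p)] for p in once] == sorted(pos[id(p)] for p in once)


def test_subsample_noop_below_cap(small_patch_set):
    out = lg.subsample_patches(small_patch_set[:40], max_n=100, seed=0)
    assert [id(p) for p in out] == [id(p) for p in small_patch_set[:40]]


def test_subsample_caps_and_is_seed_deterministic():
    patches = [_patch_with_lesion_fraction(0.0) for _ in range(250)]
    a = lg.subsample_patches(patches, max_n=100, seed=5)
    b = lg.subsample_patches(patches, max_n=100, seed=5)
    c = lg.subsample_patches(patches, max_n=100, seed=6)
    assert len(a) == 100
    assert [id(p) for p in a] == [id(p) for p in b]
    assert {id(p) for p in a} != {id(p) for p in c}


@pytest.mark.parametrize("hu,expected", [(-1024.0, 0.0), (100.0, 1.0),
                                         (-2000.0, 0.0), (-462.0, 0.5)])
def test_intensity_normalization_window(hu, expected):
    p = PatchSample(data=np.full((1, 4, 4, 4), hu), origin=(0, 0, 0),
                    lung_fraction=1.0, subject_id="t")
    out = lg.normalize_intensities(p)
    assert out.normalized
    assert out.data.flat[0] == pytest.approx(expected, abs=1e-3)
    # idempotent via the flag
    assert lg.normalize_intensities(out) is out


def test_read_pair_error_contracts(tmp_path, control_pair):
    import nibabel as nib

    from lungood.io import write_pair

    paths = write_pair(control_pair, tmp_path)
    # non-binary mask
    bad_mask = control_pair.lung_mask.astype(np.uint8).copy()
    bad_mask[0, 0, 0] = 2
    bad_path = tmp_path / "bad_mask.nii.gz"
    nib.save(nib.Nifti1Image(bad_mask, np.eye(4)), str(bad_path))
    with pytest.raises(ValueError, match="binary"):
        lg.read_pair(paths["insp_path"], paths["exp_path"], bad_path)
    # shape mismatch
    small = tmp_path / "small.nii.gz"
    nib.save(nib.Nifti1Image(np.zeros((32, 32, 32), np.float32), np.eye(4)),
             str(small))
    with pytest.raises(ValueError, match="shape"):
        lg.read_pair(paths["insp_path"], small, paths["mask_path"])
    # unreadable file
    with pytest.raises(IOError):
        lg.read_pair(tmp_path / "missing.nii.gz", paths["exp_path"],
                     paths["mask_path"])
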