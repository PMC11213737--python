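"""Patch extraction over the segmented lung: grid layout, coverage
accounting, the healthy-patch filter, per-subject subsampling and intensity
normalization.

Patches are cubic, laid on a regular grid anchored at the minimum corner of
the lung-mask bounding box, with a final clamped row per axis so the grid
reaches the bounding-box maximum. Coordinates are 0-based voxel indices;
a patch occupies the half-open box [origin, origin + edge) per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import CTVolumePair, PatchSample

__all__ = [
    "PatchGridSpec",
    "CoverageReport",
    "extract_patch_grid",
    "filter_healthy_patches",
    "subsample_patches",
    "normalize_intensities",
    "HU_WINDOW",
]

#: clipping window applied before mapping intensities to [0, 1]
HU_WINDOW = (-1024.0, 100.0)


@dataclass(frozen=True)
class PatchGridSpec:
    patch_edge: int = 50
    overlap_fraction: float = 0.2
    min_lung_fraction: float = 0.5
    coverage_target: float = 0.70
    channels: str = "insp_expR"  # or "insp_only"

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.channels not in ("insp_only", "insp_expR"):
            raise ValueError(f"unknown channels mode {self.channels!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def stride(self) -> int:
        return max(int(round(self.patch_edge * (1.0 - self.overlap_fraction))), 0)

    @property
    def n_channels(self) -> int:
        return 2 if self.channels == "insp_expR" else 1


@dataclass
class CoverageReport:
    """Fraction of lung-mask voxels covered by the union of retained patches."""

    coverage: float
    n_patches: int
    coverage_target: float

    @property
    def below_target(self) -> bool:
        return self.coverage < self.coverage_target


def _axis_origins(lo: int, hi: int, edge: int, stride: int, dim: int) -> list[int]:
    """Grid origins along one axis spanning the mask bounding box [lo, hi]."""
    last = hi - edge + 1  # origin for which the patch ends exactly at hi
    if last >= lo:
        origins = list(range(lo, last + 1, stride))
        if origins[-1] != last:
            origins.append(last)  # clamped final row reaching the bbox max
    else:
        origins = [last]  # bbox narrower than the patch; clamp below
    return sorted({int(np.clip(o, 0, dim - edge)) for o in origins})


def extract_patch_grid(pair: CTVolumePair, grid: PatchGridSpec
                       ) -> tuple[list[PatchSample], CoverageReport]:
    """Lay the patch grid over the lung and keep sufficiently lung-filled patches.

    Returns the retained patches (HU, with their cropped lung mask) and a
    coverage report. Coverage below ``coverage_target`` is flagged on the
    report and warned about, not fatal.
    """
    e = grid.patch_edge
    shape = pair.insp.shape
    if any(e > d for d in shape):
        raise ValueError(f"patch edge {e} exceeds volume shape {shape}")

    mask = pair.lung_mask
    n_lung = int(mask.sum())
    if n_lung == 0:
        report = CoverageReport(0.0, 0, grid.coverage_target)
        warnings.warn(f"{pair.subject_id}: empty lung mask, no patches extracted")
        return [], report

    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    axes_origins = [
        _axis_origins(int(lo[a]), int(hi[a]), e, grid.stride, shape[a])
        for a in range(3)
    ]

    patches: list[PatchSample] = []
    covered = np.zeros(shape, dtype=bool)
    for oz in axes_origins[0]:
        for oy in axes_origins[1]:
            for ox in axes_origins[2]:
                sl = (slice(oz, oz + e), slice(oy, oy + e), slice(ox, ox + e))
                m = mask[sl]
                lung_fraction = float(m.mean())
                if lung_fraction < grid.min_lung_fraction:
                    continue
                if grid.channels == "insp_expR":
                    data = np.stack([pair.insp[sl], pair.exp_registered[sl]])
                else:
                    data = pair.insp[sl][None]
                patches.append(PatchSample(
                    data=data, origin=(oz, oy, ox), lung_fraction=lung_fraction,
                    subject_id=pair.subject_id, lung_mask=m.copy(),
                ))
                covered[sl] = True

    coverage = float(np.count_nonzero(covered & mask)) / n_lung
    report = CoverageReport(coverage, len(patches), grid.coverage_target)
    if report.below_target:
        warnings.warn(
            f"{pair.subject_id}: patch union covers {coverage:.1%} of the lung, "
            f"below the {grid.coverage_target:.0%} target; consider lowering "
            "min_lung_fraction"
        )
    return patches, report


def filter_healthy_patches(patches: list[PatchSample],
                           emphysema_threshold_hu: float = -950.0,
                           max_emphysema_fraction: float = 0.01
                           ) -> list[PatchSample]:
    """Keep patches whose in-lung emphysema fraction is strictly below 1%.

    The fraction counts inspiratory in-lung voxels under -950 HU over
    in-lung voxels of the patch. Used when pooling "normal-appearing"
    patches for the density model; idempotent; order preserved.
    """
    kept = []
    for p in patches:
        if p.normalized:
            raise ValueError("healthy filter requires HU patches (got normalized)")
        if p.lung_mask is None:
            raise ValueError("patch carries no lung mask; re-extract with the grid")
        in_lung = p.data[0][p.lung_mask]
        if in_lung.size == 0:
            kept.append(p)
            continue
        frac = np.count_nonzero(in_lung < emphysema_threshold_hu) / in_lung.size
        if frac < max_emphysema_fraction:
            kept.append(p)
    return kept


def subsample_patches(patches: list[PatchSample], max_n: int = 100,
                      seed: int = 0) -> list[PatchSample]:
    """Uniform random cap at ``max_n`` patches; order preserved, seed-deterministic."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if len(patches) <= max_n:
        return list(patches)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(patches), size=max_n, replace=False))
    return [patches[i] for i in keep]


def normalize_intensities(patch: PatchSample) -> PatchSample:
    """Clip to [-1024, 100] HU and map affinely to [0, 1], both channels alike."""
    if patch.normalized:
        return patch
    lo, hi = HU_WINDOW
    data = (np.clip(patch.data, lo, hi) - lo) / (hi - lo)
    return PatchSample(
        data=data, origin=patch.origin, lung_fraction=patch.lung_fraction,
        subject_id=patch.subject_id, lung_mask=patch.lung_mask, normalized=True,
    )
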