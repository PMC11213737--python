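"""Synthetic paired insp/exp CT phantoms with controllable lesion burden.

The phantom stands in for cohort CT data: a two-lobe ellipsoidal lung filled
with Gaussian parenchyma noise, plus non-overlapping spherical lesions.
Emphysema-like lesions push inspiratory attenuation below the -950 HU
low-attenuation threshold; air-trapping-like lesions keep expiratory
attenuation below -856 HU while surrounding expiratory parenchyma stays
above it. Ground-truth burden is the fraction of lung voxels occupied by
lesions, so the standard LAA metrics recover it directly.

Default HU values are simulator choices placing normal tissue clearly above
both thresholds and lesions clearly below: insp parenchyma N(-850, 40),
exp parenchyma N(-750, 40), emphysema lesions N(-980, 15), air-trap lesions
N(-900, 15), background soft tissue N(30, 20).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import write_manifest, write_pair
from .types import CTVolumePair

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "save_cohort"]


class PhantomSizingError(ValueError):
    """Requested lesion geometry cannot fit inside the lung mask."""


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_axes: tuple[float, float, float] = (12.0, 15.0, 22.0)
    insp_parenchyma_mean: float = -850.0
    insp_parenchyma_sd: float = 40.0
    exp_parenchyma_mean: float = -750.0
    exp_parenchyma_sd: float = 40.0
    emphysema_burden: float = 0.0
    airtrap_burden: float = 0.0
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)
    lesion_hu_mean: float = -980.0
    background_hu: float = 30.0
    n_lesion_foci: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("emphysema_burden", "airtrap_burden"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (lo, hi) with lo <= hi")


_MAX_ATTEMPTS = 10_000
_AIRTRAP_HU_MEAN = -900.0
_LESION_SD = 15.0
_BACKGROUND_SD = 20.0


def _two_lobe_mask(spec: PhantomSpec) -> np.ndarray:
    """Two overlapping ellipsoids, symmetric about the volume centre in x."""
    shape = np.asarray(spec.volume_shape, dtype=float)
    a, b, c = spec.lung_axes
    centre = (shape - 1) / 2.0
    offset = 0.8 * a  # lobes overlap by 0.4a
    zz, yy, xx = np.meshgrid(
        *(np.arange(n, dtype=float) for n in spec.volume_shape), indexing="ij"
    )
    mask = np.zeros(spec.volume_shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        cx = centre[0] + sgn * offset
        if cx - a < 0.5 or cx + a > shape[0] - 1.5:
            raise PhantomSizingError(
                "lung ellipsoids do not fit strictly inside the volume "
                f"(semi-axis {a} at centre {cx} in dim {shape[0]})"
            )
        if centre[1] - b < 0.5 or centre[1] + b > shape[1] - 1.5:
            raise PhantomSizingError("lung semi-axis b exceeds volume bounds")
        if centre[2] - c < 0.5 or centre[2] + c > shape[2] - 1.5:
            raise PhantomSizingError("lung semi-axis c exceeds volume bounds")
        r2 = (
            ((zz - cx) / a) ** 2
            + ((yy - centre[1]) / b) ** 2
            + ((xx - centre[2]) / c) ** 2
        )
        mask |= r2 <= 1.0
    return mask


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = dz**2 + dy**2 + dx**2 <= radius**2
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def _focal_region(mask: np.ndarray, fraction: float, n_foci: int,
                  rng: np.random.Generator) -> np.ndarray:
    """The ``fraction`` of lung voxels nearest to ``n_foci`` random foci.

    Disease in COPD is regionally heterogeneous; concentrating lesions
    around a few foci leaves genuinely normal-appearing regions inside a
    diseased lung, which is what patch-level anomaly maps are meant to
    resolve.
    """
    idx = np.argwhere(mask)
    foci = idx[rng.integers(len(idx), size=n_foci)]
    d2 = np.min(((idx[:, None, :] - foci[None, :, :]) ** 2).sum(-1), axis=1)
    k = min(int(np.ceil(fraction * len(idx))), len(idx))
    region = np.zeros_like(mask)
    sel = idx[np.argsort(d2)[:k]]
    region[tuple(sel.T)] = True
    return region


def _place_lesions(mask: np.ndarray, target_voxels: int,
                   radius_range: tuple[float, float],
                   rng: np.random.Generator,
                   region: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample non-overlapping balls fully inside the lung mask.

    Candidate centres come from the mask eroded by each ball, so a placement
    attempt only fails on overlap with an already-placed lesion. Returns a
    boolean array of the placed lesion voxels; raises PhantomSizingError
    after 10,000 failed attempts.
    """
    from scipy import ndimage

    lo, hi = radius_range
    radii = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1, dtype=float)
    if radii.size == 0:
        radii = np.array([lo])
    offsets = {r: _ball_offsets(r) for r in radii}
    counts = {r: len(offsets[r]) for r in radii}
    centres: dict[float, np.ndarray] = {}
    for r in radii:
        struct = np.zeros((2 * int(r) + 1,) * 3, dtype=bool)
        struct[tuple((offsets[r] + int(r)).T)] = True
        eroded = ndimage.binary_erosion(mask, structure=struct)
        if region is not None:
            eroded &= region
        centres[r] = np.argwhere(eroded)
    radii = np.array([r for r in radii if len(centres[r])])
    if radii.size == 0:
        raise PhantomSizingError(
            f"no lesion of radius {radius_range} fits inside the lung mask"
        )
    min_count = counts[radii.min()]

    lesion = np.zeros_like(mask)
    placed = 0
    failures = 0
    while placed < target_voxels - min_count // 2:
        remaining = target_voxels - placed
        feasible = radii[
            np.array([counts[r] for r in radii]) <= max(remaining, min_count)
        ]
        r = rng.choice(feasible if feasible.size else radii[:1])
        cand = centres[r]
        centre = cand[rng.integers(len(cand))]
        idx = tuple((centre + offsets[r]).T)
        if lesion[idx].any():
            failures += 1
            if failures > _MAX_ATTEMPTS:
                raise PhantomSizingError(
                    f"could not place lesions after {_MAX_ATTEMPTS} failed "
                    "attempts; burden or lesion radius too large for the "
                    "lung geometry"
                )
            continue
        lesion[idx] = True
        placed += counts[r]
    return lesion


def generate_phantom(spec: PhantomSpec, subject_id: str = "phantom") -> CTVolumePair:
    """Generate one paired insp/exp phantom; deterministic for a fixed seed."""
    max_r = spec.lesion_radius_range[1]
    if (spec.emphysema_burden > 0 or spec.airtrap_burden > 0) and (
        max_r >= min(spec.lung_axes)
    ):
        raise PhantomSizingError(
            f"lesion radius {max_r} does not fit inside lung semi-axes {spec.lung_axes}"
        )
    rng = np.random.default_rng(spec.seed)
    mask = _two_lobe_mask(spec)
    n_lung = int(mask.sum())

    insp = rng.normal(spec.background_hu, _BACKGROUND_SD, size=spec.volume_shape)
    exp = rng.normal(spec.background_hu, _BACKGROUND_SD, size=spec.volume_shape)
    insp[mask] = rng.normal(spec.insp_parenchyma_mean, spec.insp_parenchyma_sd, n_lung)
    exp[mask] = rng.normal(spec.exp_parenchyma_mean, spec.exp_parenchyma_sd, n_lung)

    # lesion types occupy independent channels, so overlap across types is
    # allowed; within a type, spheres do not overlap. Both types share the
    # same focal disease region (emphysematous areas also trap air).
    max_burden = max(spec.emphysema_burden, spec.airtrap_burden)
    region = None
    if max_burden > 0 and spec.n_lesion_foci > 0:
        # region holds ~3x the densest lesion type, leaving rejection
        # sampling room; lesion types may overlap across channels
        frac = float(np.clip(3.0 * max_burden, 0.15, 1.0))
        if frac < 1.0:
            region = _focal_region(mask, frac, spec.n_lesion_foci, rng)
    if spec.emphysema_burden > 0:
        target = int(round(spec.emphysema_burden * n_lung))
        les = _place_lesions(mask, target, spec.lesion_radius_range, rng, region)
        insp[les] = rng.normal(spec.lesion_hu_mean, _LESION_SD, int(les.sum()))
    if spec.airtrap_burden > 0:
        target = int(round(spec.airtrap_burden * n_lung))
        les = _place_lesions(mask, target, spec.lesion_radius_range, rng, region)
        exp[les] = rng.normal(_AIRTRAP_HU_MEAN, _LESION_SD, int(les.sum()))

    label = "diseased" if spec.emphysema_burden + spec.airtrap_burden > 0 else "control"
    return CTVolumePair(
        insp=insp, exp_registered=exp, lung_mask=mask,
        spacing=spec.voxel_spacing, subject_id=subject_id, label=label,
    )


def generate_cohort(n_control: int, n_diseased: int,
                    burden_range: tuple[float, float], seed: int,
                    base_spec: PhantomSpec | None = None) -> list[CTVolumePair]:
    """Generate a labeled phantom cohort: controls first, then diseased.

    Per-subject seeds derive deterministically from the cohort seed; each
    diseased subject draws its emphysema and air-trapping burdens
    independently and uniformly from ``burden_range``.
    """
    if n_control < 0 or n_diseased < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_control + n_diseased == 0:
        raise ValueError("empty cohort: need at least one subject")
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s) for s in ss.generate_state(n_control + n_diseased)]
    burden_rng = np.random.default_rng(ss.spawn(1)[0])

    cohort: list[CTVolumePair] = []
    for i in range(n_control):
        spec = replace(base, emphysema_burden=0.0, airtrap_burden=0.0,
                       seed=subject_seeds[i] % 2**31)
        cohort.append(generate_phantom(spec, subject_id=f"control_{i:03d}"))
    lo, hi = burden_range
    for j in range(n_diseased):
        spec = replace(
            base,
            emphysema_burden=float(burden_rng.uniform(lo, hi)),
            airtrap_burden=float(burden_rng.uniform(lo, hi)),
            seed=subject_seeds[n_control + j] % 2**31,
        )
        cohort.append(generate_phantom(spec, subject_id=f"diseased_{j:03d}"))
    return cohort


def save_cohort(cohort: list[CTVolumePair], out_dir) -> str:
    """Write NIfTI triplets plus a cohort manifest CSV; returns manifest path."""
    from pathlib import Path

    out_dir = Path(out_dir)
    rows = []
    for pair in cohort:
        paths = write_pair(pair, out_dir)
        rows.append({
            "subject_id": pair.subject_id,
            "label": pair.label,
            "insp_path": paths["insp_path"],
            "exp_path": paths["exp_path"],
            "mask_path": paths["mask_path"],
        })
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    return str(manifest_path)
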