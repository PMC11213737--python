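"""Volumetric anomaly maps: reassemble patch scores into the CT geometry.

Every voxel covered by at least one patch receives the arithmetic mean of
the scores of all covering patches; voxels outside every patch are NaN
(missing). Maps are normalized for display by min-max over the 5th/95th
percentiles of a reference score population (all patch scores of the
evaluation set), clipped to [0, 1], and rendered as a red overlay on the
CT windowed to [-1300, 50] HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import matplotlib
import numpy as np

from .preproc import PatchGridSpec
from .types import AnomalyScore

__all__ = ["AnomalyMap", "build_map", "normalize_map", "render_overlay",
           "DISPLAY_WINDOW_HU"]

DISPLAY_WINDOW_HU = (-1300.0, 50.0)


@dataclass
class AnomalyMap:
    values: np.ndarray        # NaN where no patch covers the voxel
    normalized: bool = False
    p5: float | None = None
    p95: float | None = None


def build_map(patch_scores: list[AnomalyScore], grid: PatchGridSpec,
              volume_shape: tuple[int, int, int]) -> AnomalyMap:
    """Mean-accumulate patch scores into a volume aligned with the source CT."""
    e = grid.patch_edge
    total = np.zeros(volume_shape)
    count = np.zeros(volume_shape)
    for sc in patch_scores:
        oz, oy, ox = sc.origin
        if min(oz, oy, ox) < 0 or any(
            o + e > d for o, d in zip((oz, oy, ox), volume_shape)
        ):
            raise ValueError(
                f"patch origin {sc.origin} with edge {e} is out of bounds "
                f"for volume {volume_shape}"
            )
        sl = (slice(oz, oz + e), slice(oy, oy + e), slice(ox, ox + e))
        total[sl] += sc.s
        count[sl] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AnomalyMap(values=values)


def normalize_map(amap: AnomalyMap, reference_scores) -> AnomalyMap:
    """Min-max normalize by the 5th/95th percentiles of the reference scores."""
    ref = np.asarray(list(reference_scores), dtype=np.float64)
    if ref.size == 0:
        raise ValueError("reference score population is empty")
    p5, p95 = np.percentile(ref, [5, 95])
    if p95 <= p5:
        raise ValueError(f"degenerate reference: p5 == p95 == {p5}")
    vals = np.clip((amap.values - p5) / (p95 - p5), 0.0, 1.0)
    return AnomalyMap(values=vals, normalized=True, p5=float(p5), p95=float(p95))


def render_overlay(ct_volume: np.ndarray, amap: AnomalyMap, slice_axis: int = 1,
                   slice_index: int | None = None, out_path=None,
                   alpha: float = 0.5) -> np.ndarray:
    """Render one slice: windowed grayscale CT with a red-emphasizing overlay.

    Returns the uint8 RGB array; writes a PNG when ``out_path`` is given
    (byte-identical for identical inputs). Default slice axis 1 gives a
    coronal view for volumes ordered (left-right, antero-posterior,
    cranio-caudal).
    """
    if not amap.normalized:
        raise ValueError("normalize_map must be applied before rendering")
    n_slices = ct_volume.shape[slice_axis]
    if slice_index is None:
        slice_index = n_slices // 2
    if not 0 <= slice_index < n_slices:
        raise IndexError(f"slice {slice_index} out of range [0, {n_slices})")
    ct = np.take(ct_volume, slice_index, axis=slice_axis)
    ov = np.take(amap.values, slice_index, axis=slice_axis)

    lo, hi = DISPLAY_WINDOW_HU
    gray = np.clip((ct - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.stack([gray] * 3, axis=-1)
    cmap = matplotlib.colormaps["hot"]
    inside = np.isfinite(ov)
    colors = cmap(np.nan_to_num(ov))[..., :3]
    blend = np.where(inside[..., None], (1 - alpha) * rgb + alpha * colors, rgb)
    img = (np.clip(blend, 0, 1) * 255).round().astype(np.uint8)
    if out_path is not None:
        iio.imwrite(out_path, img)
    return img
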