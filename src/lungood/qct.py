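"""Quantitative CT low-attenuation metrics (LAA-950%, LAA-856%).

LAA-x% is the percentage of lung voxels with attenuation strictly below the
threshold x HU: -950 HU on inspiration is the standard emphysema surrogate,
-856 HU on registered expiration the air-trapping surrogate. Plain voxel
thresholding, no resampling or smoothing.
"""

from __future__ import annotations

import numpy as np

from .types import CTVolumePair, QCTFeatures

__all__ = ["laa_percent", "subject_qct", "EMPHYSEMA_THRESHOLD_HU", "AIRTRAP_THRESHOLD_HU"]

EMPHYSEMA_THRESHOLD_HU = -950.0
AIRTRAP_THRESHOLD_HU = -856.0


def laa_percent(volume: np.ndarray, mask: np.ndarray, threshold_hu: float) -> float:
    """Percent of mask voxels with HU strictly under ``threshold_hu``."""
    volume = np.asarray(volume)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape}, mask {mask.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: LAA percentage is undefined")
    return 100.0 * float(np.count_nonzero(volume[mask] < threshold_hu)) / n


def subject_qct(pair: CTVolumePair) -> QCTFeatures:
    """LAA-950% from the inspiratory and LAA-856% from the expiratory channel."""
    return QCTFeatures(
        laa950_pct=laa_percent(pair.insp, pair.lung_mask, EMPHYSEMA_THRESHOLD_HU),
        laa856_pct=laa_percent(pair.exp_registered, pair.lung_mask, AIRTRAP_THRESHOLD_HU),
    )
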