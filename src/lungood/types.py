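"""Shared domain containers for the anomaly-scoring pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CTVolumePair",
    "PatchSample",
    "Representation",
    "AnomalyScore",
    "PatientScore",
    "QCTFeatures",
]


@dataclass
class CTVolumePair:
    """Paired inspiratory / registered-expiratory HU volumes for one subject.

    ``exp_registered`` is assumed voxelwise-aligned to ``insp``; the pair
    shares one ``lung_mask`` and voxel ``spacing`` (mm). ``label`` is
    "control", "diseased", or "unknown" and is used for evaluation only.
    """

    insp: np.ndarray
    exp_registered: np.ndarray
    lung_mask: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str
    label: str = "unknown"

    def __post_init__(self):
        if not (self.insp.shape == self.exp_registered.shape == self.lung_mask.shape):
            raise ValueError(
                f"volume shapes disagree for {self.subject_id}: "
                f"insp {self.insp.shape}, exp {self.exp_registered.shape}, "
                f"mask {self.lung_mask.shape}"
            )
        if not np.isfinite(self.insp).all() or not np.isfinite(self.exp_registered).all():
            raise ValueError(f"non-finite HU values in {self.subject_id}")
        vals = np.unique(self.lung_mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"lung mask of {self.subject_id} is not binary (values {vals[:5]})"
            )
        self.lung_mask = self.lung_mask.astype(bool)


@dataclass
class PatchSample:
    """One cubic patch: ``data`` is (channels, e, e, e) — HU, or unitless
    after intensity normalization (``normalized`` flag)."""

    data: np.ndarray
    origin: tuple[int, int, int]
    lung_fraction: float
    subject_id: str
    lung_mask: np.ndarray | None = None
    normalized: bool = False

    @property
    def edge(self) -> int:
        return self.data.shape[-1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class Representation:
    """Latent vector z = f(x) for one patch."""

    z: np.ndarray
    subject_id: str
    origin: tuple[int, int, int]


@dataclass
class AnomalyScore:
    """Negative log likelihood of one patch representation (nats)."""

    s: float
    subject_id: str
    origin: tuple[int, int, int]


@dataclass
class PatientScore:
    """Aggregated subject-level anomaly score S(X)."""

    subject_id: str
    S: float
    strategy: str
    patch_scores: list[float] = field(default_factory=list)


@dataclass
class QCTFeatures:
    """Low-attenuation-area percentages for one subject.

    laa950_pct: % of in-lung inspiratory voxels below -950 HU (emphysema
    surrogate); laa856_pct: % of in-lung expiratory voxels below -856 HU
    (air-trapping surrogate).
    """

    laa950_pct: float
    laa856_pct: float
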