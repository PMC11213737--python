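"""NIfTI volume and cohort-manifest I/O."""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CTVolumePair

__all__ = ["read_pair", "write_pair", "read_manifest", "write_manifest"]

MANIFEST_COLUMNS = ["subject_id", "label", "insp_path", "exp_path", "mask_path"]


def _load(path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def read_pair(insp_path, exp_path, mask_path, subject_id: str | None = None,
              label: str = "unknown") -> CTVolumePair:
    """Read an inspiratory/registered-expiratory/mask triplet.

    Raises ``IOError`` for unreadable files and ``ValueError`` for shape
    mismatches or a non-binary mask (via the CTVolumePair invariants).
    Voxel spacing is taken from the inspiratory header.
    """
    insp, affine = _load(insp_path)
    exp, _ = _load(exp_path)
    mask, _ = _load(mask_path)
    if insp.shape != exp.shape or insp.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: insp {insp.shape}, exp {exp.shape}, mask {mask.shape}"
        )
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    sid = subject_id or Path(insp_path).name.split(".")[0].removesuffix("_insp")
    return CTVolumePair(
        insp=insp, exp_registered=exp, lung_mask=mask, spacing=spacing,
        subject_id=sid, label=label,
    )


def write_pair(pair: CTVolumePair, out_dir) -> dict[str, str]:
    """Write one subject as three .nii.gz files; returns the path mapping."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(pair.spacing) + [1.0])
    paths = {}
    for key, arr in (
        ("insp", pair.insp),
        ("exp", pair.exp_registered),
        ("mask", pair.lung_mask.astype(np.uint8)),
    ):
        p = out_dir / f"{pair.subject_id}_{key}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        paths[f"{key}_path"] = str(p)
    return paths


def write_manifest(rows: list[dict], path) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest rows missing columns: {missing}")
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_ids in manifest: {dupes}")
    if "split" in df.columns:
        bad = set(df["split"].dropna()) - {"train", "val", "test"}
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")
    for _, row in df.iterrows():
        for col in ("insp_path", "exp_path", "mask_path"):
            if not os.path.exists(row[col]):
                raise FileNotFoundError(
                    f"subject {row['subject_id']}: missing file {row[col]}"
                )
    return df


def load_pair_from_row(row) -> CTVolumePair:
    return read_pair(
        row["insp_path"], row["exp_path"], row["mask_path"],
        subject_id=row["subject_id"], label=row.get("label", "unknown"),
    )
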