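"""Readers and writers for the on-disk formats.

NIfTI-1 for volumes (nibabel), SPM-style 6-column plain-text motion traces
(``rp_*.txt``: translations in mm then rotations in degrees, one row per
frame), TSV manifests and reports (pandas), YAML for configuration and
ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("restalff")

__all__ = [
    "BoldSeries",
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "write_stat_map",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
    "write_provenance",
]


@dataclass
class BoldSeries:
    """One subject's 4D BOLD volume with its grid geometry."""

    data: np.ndarray  # (X, Y, Z, T)
    affine: np.ndarray
    tr_s: float
    path: str | None = field(default=None, repr=False)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def read_bold(path, tr_s: float | None = None) -> BoldSeries:
    """Load a 4D NIfTI-1 series (.nii or .nii.gz).

    ``tr_s`` overrides the header TR; a mismatch is logged, not fatal.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # corrupt header, unreadable file
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is None:
        if header_tr <= 0:
            raise ValueError(f"{path}: header carries no TR; pass tr_s explicitly")
        tr_s = header_tr
    elif header_tr > 0 and not np.isclose(header_tr, tr_s):
        logger.warning(
            "%s: header TR %.3f s differs from configured TR %.3f s; using config",
            path, header_tr, tr_s,
        )
    return BoldSeries(data=data, affine=np.asarray(img.affine), tr_s=tr_s, path=str(path))


def write_bold(path, data: np.ndarray, affine: np.ndarray, tr_s: float) -> None:
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got shape {data.shape}")
    img = nib.Nifti1Image(data.astype(np.float64), np.asarray(affine))
    zooms = list(img.header.get_zooms())
    zooms[3] = tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5, np.asarray(img.affine)


def write_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def write_stat_map(path, values: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def read_motion(path) -> np.ndarray:
    """Whitespace-delimited T x 6 motion trace."""
    trace = np.loadtxt(str(path), ndmin=2)
    if trace.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns, got {trace.shape[1]}")
    return trace


def write_motion(path, trace: np.ndarray) -> None:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be T x 6")
    np.savetxt(str(path), trace, fmt="%.8e")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(str(path), sep="\t")
    required = {"subject_id", "group"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return manifest


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(str(path), sep="\t", index=False)


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


def write_provenance(path, stage: str, config_text: str, outputs: list[str]) -> None:
    """Sidecar record tying an output to the config that produced it."""
    record = {
        "stage": stage,
        "config_sha256_16": config_hash(config_text),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
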