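"""NIfTI and table I/O helpers.

Volumes are NIfTI-1 (plain or gzipped), RAS affines, 0-based voxel
indexing; tables are CSV with declared headers. Operations that require a
shared grid check affines explicitly rather than trusting shapes alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_table",
    "read_table",
    "check_same_grid",
    "write_manifest",
    "config_hash",
]


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns ``(data, affine)`` as float64 ndarray and 4x4 affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine, dtype=float)


def check_same_grid(*affine_shape_pairs: tuple[np.ndarray, tuple[int, ...]],
                    atol: float = 1e-6) -> None:
    """Raise if any volume disagrees on shape or affine with the first."""
    (aff0, shape0), *rest = affine_shape_pairs
    for aff, shape in rest:
        if tuple(shape) != tuple(shape0):
            raise ValueError(f"grid shape mismatch: {shape} vs {shape0}")
        if not np.allclose(aff, aff0, atol=atol):
            raise ValueError("affine mismatch between volumes that must share a grid")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"malformed table {path}: missing columns {missing}")
    return df


def config_hash(config: dict) -> str:
    """Stable sha256 over the canonical JSON form of a config dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int, extra: dict | None = None) -> Path:
    import qt1pipe

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {
            "qt1pipe": qt1pipe.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
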