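"""NIfTI-1 / CSV / JSON plumbing with provenance.

Volumetric data live in NIfTI-1 with a fixed 1 x 1 x 2 mm affine (the world
frame carries no meaning for the math); flat internal arrays of shape
(n_vox, ...) map to (x, y, z, ...) volumes. Every written stage directory
receives a ``provenance.json`` recording the configuration hash, seed and
package versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

AFFINE = np.diag([1.0, 1.0, 2.0, 1.0])


def save_volume(flat: np.ndarray, shape: tuple[int, int, int], path: str | Path) -> None:
    """Write a flat (n_vox,) or (n_vox, n_t) array as a 3D/4D NIfTI-1 volume."""
    flat = np.asarray(flat)
    vol = flat.reshape(shape + flat.shape[1:])
    img = nib.Nifti1Image(vol.astype(np.float32), AFFINE)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI-1 volume back into flat (n_vox,) / (n_vox, n_t) form."""
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 3:
        return vol.reshape(-1)
    return vol.reshape(-1, vol.shape[-1])


def volume_shape(path: str | Path) -> tuple[int, int, int]:
    return tuple(nib.load(str(path)).shape[:3])


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(out_dir: str | Path, config: dict, seed: int | None) -> None:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "config_hash": config_hash(config),
        "seed": seed,
        "dcepk_version": __version__,
        "numpy_version": np.__version__,
        "config": config,
    }
    (out_dir / "provenance.json").write_text(json.dumps(record, indent=2, default=str))


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
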