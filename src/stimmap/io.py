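"""Standard-format I/O: NIfTI volumes, TCK streamlines, CSV tables, JSON reports.

Conventions, enforced here once: world coordinates are RAS in mm, voxel
indexing is 0-based, the affine rides on every volume and round-trips
bit-exact.  Vector fields are stored as 4-D NIfTI with the component axis
last; tensors as 6-component volumes in the order Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .hotspots import TRIAL_COLUMNS
from .phantom import TissueLabelVolume
from .tracking import TensorVolume


def save_label_volume(vol: TissueLabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine), str(path))


def load_label_volume(path) -> TissueLabelVolume:
    img = nib.load(str(path))
    return TissueLabelVolume(np.asarray(img.dataobj).astype(np.int16), img.affine)


def save_scalar_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_scalar_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_vector_field(field: np.ndarray, affine: np.ndarray, path) -> None:
    """(X, Y, Z, k) field as 4-D NIfTI (components along the 4th axis)."""
    if field.ndim != 4:
        raise ConfigurationError("vector field must be 4-D")
    nib.save(nib.Nifti1Image(np.asarray(field, dtype=np.float64), affine), str(path))


load_vector_field = load_scalar_volume


def save_tensor_volume(vol: TensorVolume, path) -> None:
    save_vector_field(vol.data, vol.affine, path)


def load_tensor_volume(path) -> TensorVolume:
    data, affine = load_scalar_volume(path)
    return TensorVolume(data, affine)


def save_streamlines(streamlines: list[np.ndarray], path) -> None:
    """World-mm polylines to TCK."""
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nib.streamlines.TckFile(tractogram), str(path))


def load_streamlines(path) -> list[np.ndarray]:
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in tck.tractogram.streamlines]


def save_trials(trials: pd.DataFrame, path) -> None:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ConfigurationError(f"trial table lacks column(s): {sorted(missing)}")
    trials.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"trial table lacks column(s): {sorted(missing)}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
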