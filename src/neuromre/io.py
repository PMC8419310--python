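"""File formats: NIfTI volumes, YAML configs, CSV cohort manifests.

Conventions
-----------
Arrays are ordered ``(slices, rows, cols)`` with pixel spacing
``(dz, dy, dx)`` in mm, carried in the NIfTI affine as a diagonal scaling in
that axis order. Complex wave images are stored as a trailing real/imag pair
(last axis of length 2) and recomposed on read. Masks are uint8 {0, 1};
validity is encoded as NaN in float maps where a mask is not stored alongside.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .waves import WaveField


def write_nifti(path, array, pixel_spacing_mm, dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(array)
    if dtype is not None:
        arr = arr.astype(dtype)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag(list(pixel_spacing_mm)[:3] + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def read_nifti(path):
    """Return (array, pixel_spacing_mm); raises on unreadable headers."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    except Exception as e:  # corrupt header, truncated file, ...
        raise OSError(f"cannot read NIfTI volume {path}: {e}") from e
    return arr, spacing


def write_complex_nifti(path, array, pixel_spacing_mm) -> Path:
    arr = np.asarray(array)
    stacked = np.stack([arr.real, arr.imag], axis=-1).astype(np.float64)
    return write_nifti(path, stacked, pixel_spacing_mm)


def read_complex_nifti(path):
    arr, spacing = read_nifti(path)
    if arr.shape[-1] != 2:
        raise OSError(f"{path} is not a stored complex volume "
                      "(missing real/imag pair)")
    return arr[..., 0] + 1j * arr[..., 1], spacing


def save_wavefield(wavefield: WaveField, directory, prefix: str = "wave") -> pd.DataFrame:
    """One complex NIfTI per frequency; returns a manifest table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for fi, f in enumerate(wavefield.frequencies_hz):
        p = directory / f"{prefix}_f{int(round(f))}Hz.nii.gz"
        write_complex_nifti(p, wavefield.components[fi], wavefield.pixel_spacing_mm)
        rows.append({"frequency_hz": f, "path": str(p)})
    return pd.DataFrame(rows)


def load_wavefield(manifest: pd.DataFrame) -> WaveField:
    freqs, stacks, spacing = [], [], None
    for _, row in manifest.sort_values("frequency_hz").iterrows():
        arr, sp = read_complex_nifti(row["path"])
        freqs.append(float(row["frequency_hz"]))
        stacks.append(arr)
        spacing = sp
    return WaveField(frequencies_hz=tuple(freqs), components=np.stack(stacks),
                     pixel_spacing_mm=spacing)


def _as_plain(obj):
    """Recursively convert dataclasses/tuples/numpy scalars for YAML."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(obj, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_as_plain(obj), sort_keys=True))
    return path


def load_config_dict(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_manifest(rows: list[dict], path) -> Path:
    """Cohort manifest CSV: one row per (animal, timepoint) with file paths."""
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["animal_id", "timepoint"])
    if dup.any():
        raise ValueError("animal/timepoint pairs must be unique in a manifest")
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if check_files:
        for col in df.columns:
            if not col.endswith("_path"):
                continue
            for p in df[col].dropna():
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df
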