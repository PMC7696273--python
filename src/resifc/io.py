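"""NIfTI-1 volume and TSV table round-trip helpers (nibabel / pandas)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import Bold4D, GridSpec

__all__ = [
    "save_volume",
    "load_volume",
    "save_map",
    "load_map",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]


def save_volume(path, bold: Bold4D) -> None:
    """Write a 4D volume as NIfTI-1, carrying the affine and TR."""
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float64), bold.grid.affine)
    img.header.set_zooms(tuple(bold.grid.voxel_size) + (bold.grid.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume(path) -> Bold4D:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed NIfTI at {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path} is not 4-dimensional")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    grid = GridSpec(shape=data.shape[:3], affine=np.asarray(img.affine, dtype=float), tr=tr)
    return Bold4D(data=data, grid=grid)


def save_map(path, data: np.ndarray, grid: GridSpec) -> None:
    """Write a 3D statistic/mask map as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size))
    nib.save(img, str(path))


def load_map(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = GridSpec(shape=data.shape[:3], affine=np.asarray(img.affine, dtype=float))
    return data, grid


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-separated with header; floats at full round-trip precision."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV, reporting ragged rows with their line number."""
    text = Path(path).read_text().splitlines()
    if not text:
        return pd.DataFrame()
    width = text[0].count("\t")
    for lineno, line in enumerate(text[1:], start=2):
        nfields = line.count("\t") + 1
        if line and nfields != width + 1:
            raise ValueError(
                f"{path}: ragged row at line {lineno} ({nfields} fields, expected {width + 1})"
            )
    return pd.read_csv(str(path), sep="\t")


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
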