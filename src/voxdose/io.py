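"""Volume I/O: raw little-endian binaries with text sidecar headers,
plus MetaImage (.mhd/.raw) export for viewers.

The native format mirrors what Monte Carlo dose actors emit: a flat
binary lattice and a small human-readable header carrying shape, voxel
size and dtype.  Dose maps are written as exactly two lattices — the
absorbed dose in cGy and its relative uncertainty — matching that
convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .grid import GridSpec
from .phantom import LABELS, PhantomSpec, VoxelPhantom
from .transport import DoseMap

_DTYPES = {"uint8": "<u1", "float32": "<f4", "float64": "<f8"}


def write_volume(stem: str | Path, array: np.ndarray, grid: GridSpec, meta: dict | None = None):
    """Write ``<stem>.raw`` (little-endian, C order, [x, y, z] indexing)
    and ``<stem>.hdr`` (JSON sidecar)."""
    stem = Path(stem)
    name = array.dtype.name
    if name not in _DTYPES:
        raise ValidationError(f"unsupported dtype {name}")
    header = {
        "shape": list(grid.shape),
        "voxel_side_cm": grid.voxel_side,
        "dtype": name,
        "byteorder": "little",
        "order": "C",
        "index_convention": "xyz",
    }
    if meta:
        header["meta"] = meta
    arr = np.ascontiguousarray(array, dtype=_DTYPES[name])
    stem.parent.mkdir(parents=True, exist_ok=True)
    arr.tofile(stem.with_suffix(".raw"))
    stem.with_suffix(".hdr").write_text(json.dumps(header, indent=2) + "\n")


def read_volume(stem: str | Path) -> tuple[np.ndarray, GridSpec, dict]:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".hdr").read_text())
    shape = tuple(header["shape"])
    arr = np.fromfile(stem.with_suffix(".raw"), dtype=_DTYPES[header["dtype"]])
    if arr.size != int(np.prod(shape)):
        raise ValidationError(f"raw file size does not match header shape {shape}")
    grid = GridSpec(*shape, voxel_side=header["voxel_side_cm"])
    return arr.reshape(shape), grid, header.get("meta", {})


def write_metaimage(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """Export a lattice as MetaImage (.mhd + .raw), spacing in mm."""
    import SimpleITK as sitk

    path = Path(path)
    # SimpleITK indexes arrays [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 1, 0))))
    img.SetSpacing((grid.voxel_side * 10.0,) * 3)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def write_phantom(phantom: VoxelPhantom, out_dir: str | Path, metaimage: bool = False) -> None:
    out = Path(out_dir)
    spec = phantom.spec
    meta = {
        "organ_directory": phantom.organ_directory,
        "sex": spec.sex if spec else None,
        "bmi": spec.bmi if spec else None,
        "height_m": spec.height_m if spec else None,
    }
    write_volume(out / "labels", phantom.labels, phantom.grid, meta)
    write_volume(out / "densities", phantom.densities, phantom.grid, meta)
    if metaimage:
        write_metaimage(out / "labels.mhd", phantom.labels, phantom.grid)
        write_metaimage(out / "densities.mhd", phantom.densities, phantom.grid)


def read_phantom(in_dir: str | Path) -> VoxelPhantom:
    """Read back a label/density volume pair written by write_phantom,
    or any user-supplied pair in the same format."""
    out = Path(in_dir)
    labels, grid, meta = read_volume(out / "labels")
    densities, grid2, _ = read_volume(out / "densities")
    if grid != grid2:
        raise ValidationError("label and density volumes disagree on the grid")
    directory = meta.get("organ_directory") or dict(LABELS)
    directory = {str(k): int(v) for k, v in directory.items()}
    return VoxelPhantom(
        labels=labels.astype(np.uint8),
        densities=densities.astype(np.float32),
        grid=grid,
        organ_directory=directory,
    )


def write_dose_binaries(dosemap: DoseMap, out_dir: str | Path, metaimage: bool = False) -> None:
    """Write exactly two lattices: absorbed dose (cGy, float64) and its
    relative uncertainty (float32), each with a sidecar header."""
    out = Path(out_dir)
    meta = {"units": "cGy", "n_histories": dosemap.n_histories}
    write_volume(out / "dose", dosemap.dose_cgy, dosemap.grid, meta)
    write_volume(out / "uncertainty", dosemap.relative_uncertainty, dosemap.grid, meta)
    if metaimage:
        write_metaimage(out / "dose.mhd", dosemap.dose_cgy, dosemap.grid)
        write_metaimage(out / "uncertainty.mhd", dosemap.relative_uncertainty, dosemap.grid)


def read_dose_binaries(in_dir: str | Path) -> DoseMap:
    out = Path(in_dir)
    dose, grid, meta = read_volume(out / "dose")
    unc, _, _ = read_volume(out / "uncertainty")
    return DoseMap(
        dose_cgy=dose,
        relative_uncertainty=unc.astype(np.float32),
        n_histories=int(meta.get("n_histories", 0)),
        grid=grid,
    )
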