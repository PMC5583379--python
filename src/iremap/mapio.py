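"""Reading and writing typed maps (NIfTI, float32 TIFF, CSV) and area tables.

Pixel size is the pipeline's endpoint currency (areas in mm^2), so it is
never inferred: NIfTI carries it in ``pixdim``; TIFF and CSV require a JSON
sidecar (``<stem>.json``) with the grid geometry.  Every map is written with
a ``kind`` tag and read back with the expected kind verified, so that e.g. a
conductivity map cannot silently be consumed as a field map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .damage import AreaRecord
from .grid import SCALAR_KINDS, GridSpec, ScalarMap

__all__ = ["read_map", "write_map", "read_area_table", "write_area_table"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")


def _write_sidecar(path: Path, m: ScalarMap, extra: dict | None = None) -> None:
    meta = {
        "kind": m.kind,
        "units": m.units,
        "n_x": m.grid.n_x,
        "n_y": m.grid.n_y,
        "fov_mm": m.grid.fov_mm,
        "pixel_mm": m.grid.pixel_mm,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sc} (pixel size must be explicit, never inferred)"
        )
    return json.loads(sc.read_text())


def write_map(m: ScalarMap, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a scalar map as .nii/.nii.gz, .tif/.tiff (float32) or .csv."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([m.grid.pixel_mm, m.grid.pixel_mm, 1.0, 1.0])
        img = nib.Nifti1Image(np.asarray(m.data, dtype=np.float32).T, affine)
        img.header.set_zooms((m.grid.pixel_mm, m.grid.pixel_mm))
        nib.save(img, str(path))
        _write_sidecar(path, m, extra_meta)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(m.data, dtype=np.float32))
        _write_sidecar(path, m, extra_meta)
    elif path.suffix == ".csv":
        np.savetxt(path, m.data, delimiter=",")
        _write_sidecar(path, m, extra_meta)
    else:
        raise ValueError(f"unknown map format {path.suffix!r} (use .nii[.gz], .tif, .csv)")
    return path


def read_map(path: str | Path, expected_kind: str) -> ScalarMap:
    """Read a typed scalar map and verify its kind tag and grid metadata."""
    path = Path(path)
    if expected_kind not in SCALAR_KINDS:
        raise ValueError(f"unknown expected_kind {expected_kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float).T
        sc = _sidecar_path(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
        else:
            zooms = img.header.get_zooms()
            px = float(zooms[0])
            meta = {
                "kind": expected_kind,
                "n_x": data.shape[1],
                "n_y": data.shape[0],
                "fov_mm": px * data.shape[1],
            }
    elif path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = _read_sidecar(path)
    elif path.suffix == ".csv":
        data = np.loadtxt(path, delimiter=",")
        meta = _read_sidecar(path)
    else:
        raise ValueError(f"unknown map format {path.suffix!r}")

    if meta.get("kind", expected_kind) != expected_kind:
        raise ValueError(
            f"map {path} has kind {meta.get('kind')!r}, expected {expected_kind!r}"
        )
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        locs = ", ".join(f"({r},{c})" for r, c in bad[:10])
        more = "" if len(bad) <= 10 else f" and {len(bad) - 10} more"
        raise ValueError(f"map {path} contains non-finite pixels at {locs}{more}")
    grid = GridSpec(n_x=int(meta["n_x"]), n_y=int(meta["n_y"]), fov_mm=float(meta["fov_mm"]))
    return ScalarMap(data, grid, kind=expected_kind)


AREA_COLUMNS = ["case_id", "p", "a_ire_mm2", "a_he_mm2"]


def write_area_table(records: list[AreaRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"case_id": r.case_id, "p": r.p, "a_ire_mm2": r.a_ire, "a_he_mm2": r.a_he}
            for r in records
        ],
        columns=AREA_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_area_table(path: str | Path) -> list[AreaRecord]:
    df = pd.read_csv(path)
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area table {path} missing columns {missing}")
    return [
        AreaRecord(
            p=float(row.p),
            a_ire=float(row.a_ire_mm2),
            a_he=float(row.a_he_mm2),
            case_id=str(row.case_id),
        )
        for row in df.itertuples()
    ]
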