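"""Reading and writing label volumes, meshes and result tables.

Conventions used throughout the package:

* volumes are 3D integer arrays indexed ``(z, y, x)`` — the first axis is the
  FIB-SEM sectioning axis;
* voxels are isotropic with an edge length in nanometres; the world coordinate
  of voxel ``(z, y, x)`` is ``(x, y, z) * voxel_size_nm`` (voxel-centre
  convention, 0-based), so world points are always ``(x, y, z)`` triples in nm;
* semantic roles (mother-centriole body, distal appendages, membranes, plasma
  membrane, daughter centriole) are carried in a sidecar JSON/YAML label map,
  never in format-specific headers.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "LabelVolume",
    "DEFAULT_LABEL_MAP",
    "ROLES",
    "read_label_volume",
    "write_label_volume",
    "write_mesh",
    "write_report",
]

ROLES = ("background", "mc_body", "da", "membrane", "pm", "dc")

#: Default role -> integer label assignment used by the phantom generator and
#: assumed when no sidecar label map is present.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "background": 0,
    "mc_body": 1,
    "da": 2,
    "membrane": 3,
    "pm": 4,
    "dc": 5,
}


@dataclass
class LabelVolume:
    """An isotropically sampled integer label volume.

    Parameters
    ----------
    data:
        3D integer array indexed ``(z, y, x)``.
    voxel_size_nm:
        Isotropic voxel edge length in nanometres.
    label_map:
        Mapping from role name to integer label; ``background`` must be 0.
    """

    data: np.ndarray
    voxel_size_nm: float
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D (z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel_size_nm must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        if self.label_map.get("background", 0) != 0:
            raise ValueError("background label is fixed at 0")
        present = set(np.unique(self.data)) - {0}
        known = set(self.label_map.values())
        unknown = present - known
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not present in label_map")

    def label(self, role: str) -> int:
        """Integer label for a semantic role."""
        return self.label_map[role]

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of the voxels carrying ``role``."""
        return self.data == self.label_map[role]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World ``(x, y, z)`` nm coordinates of ``(z, y, x)`` voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx[:, ::-1] * self.voxel_size_nm

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


# ---------------------------------------------------------------------------
# Minimal MRC2014 support (header words per the MRC2014 specification).
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(np.int8): 0, np.dtype(np.int16): 1, np.dtype(np.uint16): 6}


def _read_mrc(path: Path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        cella = struct.unpack("<3f", header[40:52])
        map_stamp = header[208:212]
        if map_stamp not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: missing MRC2014 'MAP ' stamp")
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        nsymbt = struct.unpack("<i", header[92:96])[0]
        fh.seek(1024 + nsymbt)
        data = np.fromfile(fh, dtype=_MRC_MODES[mode], count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    data = data.reshape(nz, ny, nx)
    # cell dimensions are in Angstrom; voxel pitch per axis
    sizes = [cella[i] / n / 10.0 for i, n in enumerate((nx, ny, nz)) if n > 0]
    if not sizes or sizes[0] <= 0:
        raise ValueError(f"{path}: MRC header has no voxel size; pass voxel_size_nm")
    if max(sizes) - min(sizes) > 1e-4 * sizes[0]:
        raise ValueError(
            f"{path}: anisotropic voxel size {sizes} nm; pass an explicit "
            "voxel_size_nm override instead of silently averaging"
        )
    return data, float(sizes[0])


def _write_mrc(path: Path, data: np.ndarray, voxel_size_nm: float) -> None:
    if data.dtype not in _MRC_MODE_OF:
        if np.issubdtype(data.dtype, np.integer):
            lo, hi = int(data.min()), int(data.max())
            if lo < np.iinfo(np.int16).min or hi > np.iinfo(np.uint16).max:
                raise ValueError("label values exceed the 16-bit range of MRC modes")
            data = data.astype(np.uint16 if hi > np.iinfo(np.int16).max else np.int16)
        else:
            raise ValueError("MRC label export requires an integer dtype")
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, _MRC_MODE_OF[data.dtype])
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    angstrom = voxel_size_nm * 10.0
    struct.pack_into("<3f", header, 40, nx * angstrom, ny * angstrom, nz * angstrom)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.astype(data.dtype, copy=False).tofile(fh)


# ---------------------------------------------------------------------------
# Sidecar metadata
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def _dump_sidecar(path: Path, volume: LabelVolume) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {"voxel_size_nm": volume.voxel_size_nm, "label_map": volume.label_map},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# Public volume I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".rec", ".map"):
        return "mrc"
    if suffix in (".tif", ".tiff"):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from extension {suffix!r}")


def read_label_volume(
    path: str | Path,
    format: str = "auto",
    voxel_size_nm: float | None = None,
    label_map: Mapping[str, int] | None = None,
) -> LabelVolume:
    """Read a label volume from an MRC file or a multi-page TIFF stack.

    The voxel size comes from the MRC header or the sidecar JSON; an explicit
    ``voxel_size_nm`` overrides both. The role->label mapping comes from the
    sidecar when present, else :data:`DEFAULT_LABEL_MAP`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    sidecar = _load_sidecar(path)
    if fmt == "mrc":
        data, header_size = _read_mrc(path)
        size = voxel_size_nm if voxel_size_nm is not None else header_size
    elif fmt == "tiff_stack":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        size = voxel_size_nm or sidecar.get("voxel_size_nm")
        if size is None:
            raise ValueError(
                f"{path}: TIFF stacks carry no voxel size; provide a sidecar "
                "labels JSON or an explicit voxel_size_nm"
            )
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(f"{path}: voxel data is not integer-valued")
    lmap = dict(label_map or sidecar.get("label_map") or DEFAULT_LABEL_MAP)
    return LabelVolume(data=data, voxel_size_nm=float(size), label_map=lmap)


def write_label_volume(volume: LabelVolume, path: str | Path, format: str = "auto") -> Path:
    """Write a label volume (plus its sidecar label map) and return the path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mrc":
        _write_mrc(path, volume.data, volume.voxel_size_nm)
    elif fmt == "tiff_stack":
        data = volume.data
        if data.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed uint16 range for TIFF export")
        # explicit photometric/planarconfig so small stacks whose y or x
        # dimension happens to be 3 or 4 are not guessed to be RGB
        tifffile.imwrite(path, data.astype(np.uint16),
                         photometric="minisblack", planarconfig="contig")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    _dump_sidecar(path, volume)
    return path


# ---------------------------------------------------------------------------
# Meshes and reports
# ---------------------------------------------------------------------------

def write_mesh(mesh, path: str | Path, format: str = "auto") -> Path:
    """Write a triangle mesh (vertex units: nm) as ASCII PLY or OBJ."""
    import trimesh

    path = Path(path)
    fmt = format if format != "auto" else path.suffix.lstrip(".").lower()
    if fmt not in ("ply", "obj"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.Trimesh(vertices=mesh[0], faces=mesh[1], process=False)
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if not np.isfinite(mesh.vertices).all():
        raise ValueError("mesh has non-finite vertices")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    return path


def write_report(report, path: str | Path, format: str = "auto") -> Path:
    """Write per-component / per-cell results as CSV or a lossless JSON."""
    import pandas as pd

    path = Path(path)
    fmt = format if format != "auto" else path.suffix.lstrip(".").lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        return path
    if fmt == "csv":
        if hasattr(report, "to_frame"):
            frame = report.to_frame()
        elif isinstance(report, pd.DataFrame):
            frame = report
        else:
            frame = pd.DataFrame(report)
        frame.to_csv(path, index=False)
        return path
    raise ValueError(f"unsupported report format {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
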