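"""Volume and table I/O.

Volumes are written as NRRD (built-in minimal raw-encoding codec) or NIfTI
(via nibabel), chosen by file extension.  Arrays are indexed ``[x, y, z]``
in LPS world axes with a diagonal index→world mapping
``world = origin + index * spacing``; only such volumes are accepted on
read.  Node tables are plain CSV, level tables and density metadata are
JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityMap, KdeConfig
from .grid import TemplateGrid
from .mapping import DisplacementField
from .records import NODE_COLUMNS, NodeRecord, frame_to_nodes, nodes_to_frame
from .template import LevelAtlas, LevelInfo

_NRRD_TYPES = {
    "int16": np.int16,
    "short": np.int16,
    "int32": np.int32,
    "int": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NUMPY_TO_NRRD = {
    np.dtype(np.int16): "int16",
    np.dtype(np.int32): "int32",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def _write_nrrd(path: Path, array: np.ndarray, grid: TemplateGrid, vector: bool) -> None:
    dtype = np.dtype(array.dtype)
    if dtype not in _NUMPY_TO_NRRD:
        raise ValueError(f"unsupported dtype {dtype}")
    sx, sy, sz = grid.spacing
    if vector:
        # component axis first, fastest-varying in the raw stream
        data = np.moveaxis(array, -1, 0)
        sizes = f"3 {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}"
        directions = f"none ({sx},0,0) (0,{sy},0) (0,0,{sz})"
        kinds = "vector domain domain domain"
        dim = 4
    else:
        data = array
        sizes = f"{grid.shape[0]} {grid.shape[1]} {grid.shape[2]}"
        directions = f"({sx},0,0) (0,{sy},0) (0,0,{sz})"
        kinds = "domain domain domain"
        dim = 3
    header = (
        "NRRD0004\n"
        f"type: {_NUMPY_TO_NRRD[dtype]}\n"
        f"dimension: {dim}\n"
        "space: left-posterior-superior\n"
        f"sizes: {sizes}\n"
        f"space directions: {directions}\n"
        f"kinds: {kinds}\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({grid.origin[0]},{grid.origin[1]},{grid.origin[2]})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(data).tobytes(order="F"))


def _read_nrrd(path: Path) -> tuple[np.ndarray, TemplateGrid, bool]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path} is not a NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding") != "raw":
            raise ValueError("only raw NRRD encoding is supported")
        if fields.get("endian", "little") != "little":
            raise ValueError("only little-endian NRRD is supported")
        dtype = _NRRD_TYPES.get(fields.get("type", ""))
        if dtype is None:
            raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
        sizes = [int(v) for v in fields["sizes"].split()]
        raw = np.frombuffer(fh.read(), dtype=dtype)
    vector = len(sizes) == 4
    if vector and sizes[0] != 3:
        raise ValueError("vector NRRD must have 3 components first")
    array = raw.reshape(sizes, order="F")
    spatial = sizes[1:] if vector else sizes
    dirs = [
        v
        for v in fields.get("space directions", "").replace("none", "").split(")")
        if v.strip()
    ]
    spacing = []
    for axis, chunk in enumerate(dirs):
        nums = [float(x) for x in chunk.strip().lstrip("(").split(",")]
        spacing.append(nums[axis])
    origin_txt = fields.get("space origin", "(0,0,0)").strip().strip("()")
    origin = tuple(float(x) for x in origin_txt.split(","))
    grid = TemplateGrid(tuple(spatial), tuple(spacing), origin)
    if vector:
        array = np.moveaxis(array, 0, -1)
    return np.ascontiguousarray(array), grid, vector


def _write_nifti(path: Path, array: np.ndarray, grid: TemplateGrid, vector: bool) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    data = array if not vector else array  # 4th axis = components
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, TemplateGrid, bool]:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError("only diagonal (axis-aligned LPS) affines are supported")
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    array = np.asanyarray(img.dataobj)
    vector = array.ndim == 4
    shape = array.shape[:3]
    return (
        np.ascontiguousarray(array),
        TemplateGrid(shape, spacing, origin),
        vector,
    )


def _is_nrrd(path: Path) -> bool:
    return path.suffix == ".nrrd"


def write_volume(path, array: np.ndarray, grid: TemplateGrid) -> None:
    path = Path(path)
    vector = array.ndim == 4
    if _is_nrrd(path):
        _write_nrrd(path, array, grid, vector)
    else:
        _write_nifti(path, array, grid, vector)


def read_volume(path) -> tuple[np.ndarray, TemplateGrid, bool]:
    path = Path(path)
    return _read_nrrd(path) if _is_nrrd(path) else _read_nifti(path)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii", ".nrrd"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_atlas(path, atlas: LevelAtlas) -> None:
    path = Path(path)
    write_volume(path, atlas.labels.astype(np.int16), atlas.grid)
    volumes = atlas.volumes_cm3
    table = [
        {
            "label": e.label,
            "name": e.name,
            "side": e.side,
            "consensus": e.consensus,
            "volume_cm3": volumes[e.label],
        }
        for e in atlas.table
    ]
    _sidecar(path).write_text(json.dumps({"levels": table}, indent=2))


def read_atlas(path) -> LevelAtlas:
    path = Path(path)
    labels, grid, vector = read_volume(path)
    if vector:
        raise ValueError("atlas volume must be scalar")
    meta = json.loads(_sidecar(path).read_text())
    table = tuple(
        LevelInfo(int(e["label"]), e["name"], e["side"], bool(e["consensus"]))
        for e in meta["levels"]
    )
    return LevelAtlas(grid, labels.astype(np.int16), table)


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------


def write_density(path, density: DensityMap) -> None:
    path = Path(path)
    write_volume(path, density.values.astype(np.float32), density.grid)
    meta = {
        "units": density.config.output_units,
        "bandwidth_mm": density.config.bandwidth_mm,
        "kernel": density.config.kernel,
        "p_norm": density.config.p_norm,
        "smoothing_sigma_mm": density.config.smoothing_sigma_mm,
        "n_nodes": density.n_nodes,
        "n_patients": density.n_patients,
        "total_mass_permille": density.total_mass_permille,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_density(path) -> DensityMap:
    path = Path(path)
    values, grid, vector = read_volume(path)
    if vector:
        raise ValueError("density volume must be scalar")
    meta = json.loads(_sidecar(path).read_text())
    cfg = KdeConfig(
        bandwidth_mm=meta["bandwidth_mm"],
        kernel=meta["kernel"],
        p_norm=meta["p_norm"],
        smoothing_sigma_mm=meta["smoothing_sigma_mm"],
    )
    return DensityMap(
        grid=grid,
        values=values.astype(float),
        config=cfg,
        n_nodes=int(meta["n_nodes"]),
        n_patients=int(meta["n_patients"]),
    )


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------


def write_dvf(path, field: DisplacementField) -> None:
    path = Path(path)
    write_volume(path, field.vectors.astype(np.float32), field.grid)
    _sidecar(path).write_text(json.dumps({"direction": field.direction}, indent=2))


def read_dvf(path) -> DisplacementField:
    path = Path(path)
    vectors, grid, vector = read_volume(path)
    if not vector:
        raise ValueError("displacement field volume must have 3 components")
    meta = json.loads(_sidecar(path).read_text())
    return DisplacementField(grid, vectors.astype(float), meta["direction"])


# ---------------------------------------------------------------------------
# Node tables
# ---------------------------------------------------------------------------


def write_nodes(path, nodes) -> None:
    nodes_to_frame(nodes).to_csv(path, index=False)


def read_nodes(path) -> list[NodeRecord]:
    frame = pd.read_csv(path)
    missing = set(NODE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    return frame_to_nodes(frame)
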