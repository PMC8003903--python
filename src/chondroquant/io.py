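"""File formats: NIfTI multi-echo volumes, PLY/OBJ meshes, CSV tables, and
DICOM geometry-header extraction.

Multi-echo volumes are stored as a single 4D NIfTI (echo along the fourth
axis) with a JSON sidecar carrying the echo times; per-echo 3D files are
accepted on read.  DICOM support is read-only and limited to the spatial
calibration tags (a deliberately small explicit-VR little-endian parser --
only header geometry is ever needed).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import VolumeGeometry
from .meshmodel import SurfaceMesh
from .relaxometry import MultiEchoVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_table",
    "write_table",
    "dicom_geometry",
    "geometry_from_affine",
]


# ---------------------------------------------------------------------------
# volumes


def geometry_from_affine(affine: np.ndarray, dims: Sequence[int]) -> VolumeGeometry:
    m = np.asarray(affine, dtype=float)[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return VolumeGeometry(
        origin=tuple(np.asarray(affine)[:3, 3]),
        spacing=tuple(spacing),
        dims=tuple(int(d) for d in dims[:3]),
        direction=direction,
    )


def write_volume(volume: MultiEchoVolume, path: str | Path) -> Path:
    """Write a 4D NIfTI plus a ``.json`` sidecar with the echo times."""
    path = Path(path)
    data = np.moveaxis(volume.signals, 0, -1)
    img = nib.Nifti1Image(data, volume.geometry.affine)
    nib.save(img, str(path))
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps({"echo_times_ms": list(volume.echo_times)}, indent=2))
    return path


def read_volume(
    path: str | Path | Sequence[str | Path],
    echo_times: Sequence[float] | None = None,
) -> MultiEchoVolume:
    """Read a 4D NIfTI (with sidecar) or a list of per-echo 3D NIfTI files.

    For per-echo files ``echo_times`` is required and all files must share
    geometry.
    """
    if isinstance(path, (str, Path)):
        path = Path(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
        if echo_times is None:
            sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
            if not sidecar.exists():
                raise ValueError(f"{path}: echo_times not given and sidecar {sidecar} missing")
            echo_times = json.loads(sidecar.read_text())["echo_times_ms"]
        geom = geometry_from_affine(img.affine, data.shape)
        return MultiEchoVolume(
            echo_times=np.asarray(echo_times, dtype=float),
            signals=np.moveaxis(data, -1, 0),
            geometry=geom,
        )
    # per-echo files
    if echo_times is None:
        raise ValueError("echo_times required when reading per-echo files")
    vols, geom = [], None
    for p in path:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{p}: expected 3D per-echo volume")
        g = geometry_from_affine(img.affine, data.shape)
        if geom is None:
            geom = g
        elif not g.approx_equal(geom):
            raise ValueError(f"{p}: geometry differs across echoes")
        vols.append(data)
    return MultiEchoVolume(
        echo_times=np.asarray(echo_times, dtype=float), signals=np.stack(vols), geometry=geom
    )


def write_scalar_volume(data: np.ndarray, geometry: VolumeGeometry, path: str | Path) -> Path:
    """Write a single 3D scalar map (e.g. a T2 or validity map)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), geometry.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# meshes


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write ASCII PLY (``.ply``) or Wavefront OBJ (``.obj``)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        lines = [
            "ply", "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property double x", "property double y", "property double z",
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        for v in mesh.vertices:
            lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
        for f in mesh.faces:
            lines.append(f"3 {f[0]} {f[1]} {f[2]}")
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix.lower() == ".obj":
        lines = [f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}" for v in mesh.vertices]
        lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    if path.suffix.lower() == ".obj":
        return _read_obj(path)
    raise ValueError(f"unsupported mesh format {path.suffix!r}")


def _read_ply(path: Path) -> SurfaceMesh:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = None
    i = 1
    fmt = None
    while i < len(text):
        line = text[i].strip()
        i += 1
        if line.startswith("format"):
            fmt = line.split()[1]
        elif line.startswith("element vertex"):
            n_vert = int(line.split()[-1])
        elif line.startswith("element face"):
            n_face = int(line.split()[-1])
        elif line == "end_header":
            break
    if fmt != "ascii":
        raise ValueError(f"{path}: only ASCII PLY is supported (format={fmt})")
    if n_vert is None or n_face is None:
        raise ValueError(f"{path}: missing element counts in header")
    verts = np.array(
        [[float(x) for x in text[i + j].split()[:3]] for j in range(n_vert)]
    )
    faces = []
    for j in range(n_face):
        parts = text[i + n_vert + j].split()
        if int(parts[0]) != 3:
            raise ValueError(f"{path}: face {j} is not a triangle")
        faces.append([int(p) for p in parts[1:4]])
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


def _read_obj(path: Path) -> SurfaceMesh:
    verts, faces = [], []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: only triangular faces supported")
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    if not verts:
        raise ValueError(f"{path}: no vertices found")
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# tables


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path, allow_missing: bool = False) -> pd.DataFrame:
    """Read an RFC-4180 CSV; by default any missing cell is an error naming
    the offending row and column."""
    path = Path(path)
    df = pd.read_csv(path)
    if not allow_missing:
        na = df.isna()
        if na.to_numpy().any():
            row = int(na.any(axis=1).idxmax())
            col = na.loc[row][na.loc[row]].index[0]
            raise ValueError(f"{path}: missing cell at row {row}, column {col!r}")
    return df


# ---------------------------------------------------------------------------
# DICOM geometry


_GEOMETRY_TAGS = {
    (0x0018, 0x0050): "SliceThickness",
    (0x0018, 0x0088): "SpacingBetweenSlices",
    (0x0020, 0x0032): "ImagePositionPatient",
    (0x0020, 0x0037): "ImageOrientationPatient",
    (0x0028, 0x0010): "Rows",
    (0x0028, 0x0011): "Columns",
    (0x0028, 0x0030): "PixelSpacing",
}

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}


def _parse_dicom_elements(raw: bytes) -> dict[str, object]:
    """Walk explicit-VR little-endian data elements, keeping geometry tags."""
    pos = 0
    if len(raw) > 132 and raw[128:132] == b"DICM":
        pos = 132
    out: dict[str, object] = {}
    while pos + 8 <= len(raw):
        group, elem = struct.unpack_from("<HH", raw, pos)
        vr = raw[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            value_at = pos + 12
        else:
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            value_at = pos + 8
        if (group, elem) == (0x7FE0, 0x0010):
            break
        value = raw[value_at : value_at + length]
        name = _GEOMETRY_TAGS.get((group, elem))
        if name is not None:
            if vr == b"US":
                out[name] = struct.unpack("<H", value[:2])[0]
            elif vr == b"DS":
                out[name] = [float(x) for x in value.decode("ascii").strip("\x00 ").split("\\")]
            else:
                raise ValueError(f"unexpected VR {vr!r} for tag ({group:04x},{elem:04x})")
        pos = value_at + length
    return out


def dicom_geometry(path: str | Path, n_slices: int = 1) -> VolumeGeometry:
    """Extract spatial calibration from a DICOM slice header.

    Axis convention of the returned geometry: index axis 0 runs along the
    image row direction (first orientation triplet, column spacing), axis 1
    along the column direction (second triplet, row spacing), axis 2 along
    their cross product with the slice spacing (SpacingBetweenSlices if
    present, else SliceThickness).
    """
    raw = Path(path).read_bytes()
    tags = _parse_dicom_elements(raw)
    missing = {"ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing", "Rows", "Columns"} - set(tags)
    if missing:
        raise ValueError(f"{path}: missing DICOM geometry tags {sorted(missing)}")
    orient = np.asarray(tags["ImageOrientationPatient"], dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    ps = tags["PixelSpacing"]  # [between-rows, between-columns]
    slice_spacing = tags.get("SpacingBetweenSlices", tags.get("SliceThickness", [1.0]))[0]
    direction = np.column_stack([row_dir, col_dir, normal])
    return VolumeGeometry(
        origin=tuple(tags["ImagePositionPatient"]),
        spacing=(float(ps[1]), float(ps[0]), float(slice_spacing)),
        dims=(int(tags["Columns"]), int(tags["Rows"]), int(n_slices)),
        direction=direction,
    )
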