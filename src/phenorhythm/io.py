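"""Point-cloud readers and writers: ASCII XYZ(L), binary PLY, LAS (read-only).

XYZ files are whitespace-separated ``x y z [label [plant_id]]`` with ``#``
comment lines, written at 1e-6 m precision.  PLY is binary little-endian
with double-precision coordinates (lossless round trip) and optional integer
``label`` / ``plant_id`` properties.  LAS 1.2+ reading applies the header's
scale and offset; only coordinates are kept.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .cloud import PointCloud

__all__ = ["read_cloud", "write_cloud"]

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class CloudFormatError(ValueError):
    """Raised for malformed point-cloud files."""


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xyz", "txt", "xyzl"):
        return "xyz"
    if suffix in ("ply", "las"):
        return suffix
    raise CloudFormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud; coordinates are returned in meters.

    ``format`` is one of ``xyz`` / ``ply`` / ``las``, inferred from the file
    suffix when omitted.  Labels and plant ids are preserved when present.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "las":
        return _read_las(path)
    raise CloudFormatError(f"unknown format {fmt!r}")


def write_cloud(cloud: PointCloud, path, format: Optional[str] = None) -> None:
    """Write a cloud as ASCII XYZ(L) or binary little-endian PLY."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    else:
        raise CloudFormatError(f"cannot write format {fmt!r}")


# --------------------------------------------------------------------------
# ASCII XYZ(L)
# --------------------------------------------------------------------------

def _read_xyz(path: Path) -> PointCloud:
    coords, labels, plants = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if ncols is None:
                if len(parts) not in (3, 4, 5):
                    raise CloudFormatError(
                        f"{path.name}:{lineno}: expected 3-5 columns, got {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise CloudFormatError(
                    f"{path.name}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise CloudFormatError(f"{path.name}:{lineno}: non-numeric value ({exc})") from None
            coords.append(vals[:3])
            if ncols >= 4:
                labels.append(int(vals[3]))
            if ncols == 5:
                plants.append(int(vals[4]))
    xyz = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    return PointCloud(
        xyz,
        np.asarray(labels, dtype=np.int64) if labels else None,
        np.asarray(plants, dtype=np.int64) if plants else None,
    )


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    cols = [cloud.xyz]
    fmt = ["%.6f", "%.6f", "%.6f"]
    header = "x y z"
    if cloud.labels is not None:
        cols.append(cloud.labels[:, None].astype(np.float64))
        fmt.append("%d")
        header += " label"
    if cloud.plant_ids is not None:
        cols.append(cloud.plant_ids[:, None].astype(np.float64))
        fmt.append("%d")
        header += " plant_id"
    data = np.hstack(cols) if len(cloud) else np.empty((0, len(fmt)))
    np.savetxt(path, data, fmt=" ".join(fmt), header=header, comments="# ")


# --------------------------------------------------------------------------
# PLY (binary little-endian; ASCII also readable)
# --------------------------------------------------------------------------

def _write_ply(cloud: PointCloud, path: Path) -> None:
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    props = ["property double x", "property double y", "property double z"]
    if cloud.labels is not None:
        fields.append(("label", "<i4"))
        props.append("property int label")
    if cloud.plant_ids is not None:
        fields.append(("plant_id", "<i4"))
        props.append("property int plant_id")
    rec = np.empty(len(cloud), dtype=fields)
    rec["x"], rec["y"], rec["z"] = cloud.x, cloud.y, cloud.z
    if cloud.labels is not None:
        rec["label"] = cloud.labels
    if cloud.plant_ids is not None:
        rec["plant_id"] = cloud.plant_ids
    header = "\n".join(
        ["ply", "format binary_little_endian 1.0", f"element vertex {len(cloud)}"]
        + props
        + ["end_header", ""]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise CloudFormatError(f"{path.name}: not a PLY file")
        fmt_line = fh.readline().split()
        if len(fmt_line) < 2 or fmt_line[0] != b"format":
            raise CloudFormatError(f"{path.name}: missing PLY format line")
        binary = fmt_line[1] == b"binary_little_endian"
        if not binary and fmt_line[1] != b"ascii":
            raise CloudFormatError(f"{path.name}: unsupported PLY format {fmt_line[1].decode()}")

        n_vertex = None
        fields = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path.name}: truncated PLY header")
            parts = line.split()
            if not parts or parts[0] == b"comment":
                continue
            if parts[0] == b"element":
                in_vertex = parts[1] == b"vertex"
                if in_vertex:
                    n_vertex = int(parts[2])
                elif int(parts[2]) != 0:
                    raise CloudFormatError(f"{path.name}: only vertex elements supported")
            elif parts[0] == b"property" and in_vertex:
                if parts[1] == b"list":
                    raise CloudFormatError(f"{path.name}: list properties not supported")
                tname = parts[1].decode()
                if tname not in _PLY_TYPES:
                    raise CloudFormatError(f"{path.name}: unknown PLY type {tname!r}")
                fields.append((parts[2].decode(), "<" + _PLY_TYPES[tname]))
            elif parts[0] == b"end_header":
                break
        if n_vertex is None:
            raise CloudFormatError(f"{path.name}: no vertex element")

        dtype = np.dtype(fields)
        if binary:
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype, count=n_vertex)
        else:
            rec = np.loadtxt(fh, dtype=dtype, max_rows=n_vertex, ndmin=1)

    names = [f[0] for f in fields]
    for axis in "xyz":
        if axis not in names:
            raise CloudFormatError(f"{path.name}: missing coordinate property {axis!r}")
    xyz = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)
    labels = rec["label"].astype(np.int64) if "label" in names else None
    plants = rec["plant_id"].astype(np.int64) if "plant_id" in names else None
    return PointCloud(xyz, labels, plants)


# --------------------------------------------------------------------------
# LAS (read-only, versions 1.2 - 1.4)
# --------------------------------------------------------------------------

def _read_las(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header = fh.read(375)
        if len(header) < 227 or header[:4] != b"LASF":
            raise CloudFormatError(f"{path.name}: not a LAS file")
        ver_major, ver_minor = header[24], header[25]
        if ver_major != 1:
            raise CloudFormatError(f"{path.name}: unsupported LAS version {ver_major}.{ver_minor}")
        (offset_to_points,) = struct.unpack_from("<I", header, 96)
        record_len = struct.unpack_from("<H", header, 105)[0]
        (n_legacy,) = struct.unpack_from("<I", header, 107)
        sx, sy, sz = struct.unpack_from("<3d", header, 131)
        ox, oy, oz = struct.unpack_from("<3d", header, 155)
        n_points = n_legacy
        if n_points == 0 and ver_minor >= 4 and len(header) >= 255:
            (n_points,) = struct.unpack_from("<Q", header, 247)

        fh.seek(offset_to_points)
        raw = fh.read(record_len * n_points)
    if len(raw) < record_len * n_points:
        raise CloudFormatError(f"{path.name}: truncated point data")
    rec = np.frombuffer(raw, dtype=np.uint8).reshape(n_points, record_len)
    ints = rec[:, :12].copy().view("<i4").reshape(n_points, 3)
    xyz = ints.astype(np.float64) * [sx, sy, sz] + [ox, oy, oz]
    return PointCloud(xyz)
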