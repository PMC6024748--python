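"""Point-cloud containers and readers/writers for ASCII XYZ, PLY and LAS 1.2.

All coordinates are in meters with z up.  Per-point plant labels are
non-negative integers with 0 reserved for ground/unassigned points; they ride
along as a 4th XYZ column, a ``plant_label`` vertex property in PLY, and the
``point_source_id`` field in LAS.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["PointCloud", "read_cloud", "write_cloud", "ParseError"]


class ParseError(ValueError):
    """A file does not conform to the named point-cloud standard."""


@dataclass
class PointCloud:
    """Points in meters with optional per-point plant labels.

    Parameters
    ----------
    xyz
        ``(n, 3)`` float array of coordinates in meters.
    plant_label
        Optional ``(n,)`` array of non-negative integer plant identities;
        0 means ground / not assigned to any plant.
    source_frame
        Identifier of the rotation frame the coordinates live in
        (``"world"`` unless the cloud has been rotated for slicing).
    """

    xyz: np.ndarray
    plant_label: Optional[np.ndarray] = None
    source_frame: str = "world"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.plant_label is not None:
            self.plant_label = np.asarray(self.plant_label, dtype=np.int64).ravel()
            if self.plant_label.shape[0] != self.xyz.shape[0]:
                raise ValueError(
                    f"plant_label length {self.plant_label.shape[0]} != "
                    f"point count {self.xyz.shape[0]}"
                )
            if self.plant_label.size and self.plant_label.min() < 0:
                raise ValueError("plant labels must be non-negative (0 = no plant)")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Labels as an array, zeros when the cloud carries none."""
        if self.plant_label is None:
            return np.zeros(len(self), dtype=np.int64)
        return self.plant_label

    def select(self, index) -> "PointCloud":
        """Subset of the cloud at ``index`` (any numpy fancy index)."""
        lab = None if self.plant_label is None else self.plant_label[index]
        return PointCloud(self.xyz[index], lab, source_frame=self.source_frame)

    def plant_ids(self) -> np.ndarray:
        """Sorted distinct nonzero labels present in the cloud."""
        lab = self.labels
        ids = np.unique(lab)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# ASCII XYZ
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> PointCloud:
    rows = []
    labels = []
    has_label = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "//")):
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from None
            row_has_label = len(parts) >= 4
            if has_label is None:
                has_label = row_has_label
            elif has_label != row_has_label:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            rows.append((x, y, z))
            if row_has_label:
                try:
                    labels.append(int(float(parts[3])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad label column: {exc}") from None
    xyz = np.array(rows, dtype=np.float64).reshape(-1, 3)
    lab = np.array(labels, dtype=np.int64) if has_label else None
    return PointCloud(xyz, lab)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.plant_label is not None:
            for (x, y, z), l in zip(cloud.xyz, cloud.plant_label):
                fh.write(f"{x:.7f} {y:.7f} {z:.7f} {int(l)}\n")
        else:
            for x, y, z in cloud.xyz:
                fh.write(f"{x:.7f} {y:.7f} {z:.7f}\n")


# ---------------------------------------------------------------------------
# PLY (ASCII and binary little-endian), vertex element only
# ---------------------------------------------------------------------------

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


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ParseError(f"{path}: missing 'ply' magic line")
        fmt = None
        elements = []  # (name, count, [(prop_name, np_type)])
        while True:
            raw = fh.readline()
            if not raw:
                raise ParseError(f"{path}: header ended before end_header")
            line = raw.decode("ascii", "replace").strip()
            if not line or line.startswith("comment"):
                continue
            tok = line.split()
            if tok[0] == "format":
                fmt = tok[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    raise ParseError(f"{path}: list properties unsupported on vertices")
                if tok[1] not in _PLY_TYPES:
                    raise ParseError(f"{path}: unknown property type {tok[1]!r}")
                elements[-1][2].append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise ParseError(f"{path}: no vertex element")
        _, count, props = vertex
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ParseError(f"{path}: vertex element lacks property {axis!r}")
        dtype = np.dtype([(n, ("<" + t) if fmt != "ascii" else t) for n, t in props])
        if fmt == "ascii":
            data = np.zeros(count, dtype=dtype)
            for i in range(count):
                line = fh.readline().decode("ascii", "replace").split()
                if len(line) < len(props):
                    raise ParseError(f"{path}: vertex record {i}: too few values")
                for (n, _), v in zip(props, line):
                    data[n][i] = float(v)
        else:
            buf = fh.read(count * dtype.itemsize)
            if len(buf) < count * dtype.itemsize:
                raise ParseError(f"{path}: truncated binary vertex data")
            data = np.frombuffer(buf, dtype=dtype, count=count)
    xyz = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    lab = None
    if "plant_label" in names:
        lab = data["plant_label"].astype(np.int64)
    return PointCloud(xyz, lab)


def _write_ply(cloud: PointCloud, path: Path, text: bool = False) -> None:
    n = len(cloud)
    labeled = cloud.plant_label is not None
    header = ["ply",
              "format ascii 1.0" if text else "format binary_little_endian 1.0",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    if labeled:
        header.append("property int plant_label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if text:
            lines = []
            for i in range(n):
                x, y, z = cloud.xyz[i]
                row = f"{x:.9g} {y:.9g} {z:.9g}"
                if labeled:
                    row += f" {int(cloud.plant_label[i])}"
                lines.append(row)
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))
        else:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if labeled:
                fields.append(("plant_label", "<i4"))
            rec = np.zeros(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.xyz[:, 0], cloud.xyz[:, 1], cloud.xyz[:, 2]
            if labeled:
                rec["plant_label"] = cloud.plant_label
            fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# LAS 1.2, point data record format 0 (20 bytes)
# ---------------------------------------------------------------------------

_LAS_SCALE = 1e-6  # micrometer resolution; preserves the 1e-6 m round-trip contract


def _read_las(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header = fh.read(227)
        if len(header) < 227 or header[:4] != b"LASF":
            raise ParseError(f"{path}: not a LAS file (missing LASF signature)")
        offset_to_points = struct.unpack_from("<I", header, 96)[0]
        point_format = header[104]
        record_len = struct.unpack_from("<H", header, 105)[0]
        n_points = struct.unpack_from("<I", header, 107)[0]
        sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", header, 131)
        if point_format & 0x3F not in (0, 1, 2, 3):
            raise ParseError(f"{path}: unsupported point data format {point_format}")
        if record_len < 20:
            raise ParseError(f"{path}: point record length {record_len} < 20")
        fh.seek(offset_to_points)
        buf = fh.read(n_points * record_len)
        if len(buf) < n_points * record_len:
            raise ParseError(f"{path}: truncated point data")
    rec = np.frombuffer(buf, dtype=np.uint8).reshape(n_points, record_len) if n_points \
        else np.zeros((0, record_len), dtype=np.uint8)
    ints = rec[:, 0:12].copy().view("<i4").reshape(n_points, 3) if n_points \
        else np.zeros((0, 3), dtype=np.int32)
    xyz = ints.astype(np.float64) * np.array([sx, sy, sz]) + np.array([ox, oy, oz])
    psid = rec[:, 18:20].copy().view("<u2").ravel().astype(np.int64) if n_points \
        else np.zeros(0, dtype=np.int64)
    # point_source_id carries the plant label; an all-zero column is "unlabeled"
    lab = psid if psid.any() else None
    return PointCloud(xyz, lab)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    if n:
        mins = cloud.xyz.min(axis=0)
        maxs = cloud.xyz.max(axis=0)
    else:
        mins = maxs = np.zeros(3)
    offset = np.floor(mins)
    span = (maxs - offset).max() if n else 0.0
    scale = _LAS_SCALE
    if span / scale > 2**31 - 1:  # very large extents: coarsen to stay in int32
        scale = span / (2**31 - 2)
    header = bytearray(227)
    header[0:4] = b"LASF"
    struct.pack_into("<B", header, 24, 1)   # version major
    struct.pack_into("<B", header, 25, 2)   # version minor
    struct.pack_into("<H", header, 94, 227)  # header size
    struct.pack_into("<I", header, 96, 227)  # offset to point data
    struct.pack_into("<B", header, 104, 0)  # point data format 0
    struct.pack_into("<H", header, 105, 20)  # record length
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<6d", header, 131, scale, scale, scale, *offset)
    struct.pack_into("<6d", header, 179,
                     maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])
    rec = np.zeros((n, 20), dtype=np.uint8)
    if n:
        ints = np.round((cloud.xyz - offset) / scale).astype("<i4")
        rec[:, 0:12] = ints.astype("<i4").view(np.uint8).reshape(n, 12)
        labels = np.clip(cloud.labels, 0, 65535).astype("<u2")
        rec[:, 18:20] = labels.view(np.uint8).reshape(n, 2)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = ("xyz", "ply", "las")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt == "laz":
            raise ValueError("compressed LAZ is not supported; decompress to LAS first")
        if fmt not in _FORMATS:
            raise ValueError(f"unknown point-cloud format {fmt!r}; choose from {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "laz":
        raise ValueError("compressed LAZ is not supported; decompress to LAS first")
    if suffix in _FORMATS:
        return suffix
    if suffix in ("txt", "pts", "asc"):
        return "xyz"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format= explicitly")


def read_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from ``path`` in XYZ, PLY or LAS format.

    The format is inferred from the file suffix unless given explicitly.
    Coordinates are returned in meters; a label column/field becomes
    ``plant_label`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    return _read_las(path)


def write_cloud(cloud: PointCloud, path, format: Optional[str] = None,
                ply_text: bool = False) -> Path:
    """Write ``cloud`` to ``path``; labels are stored as a per-point attribute.

    ``ply_text=True`` selects ASCII PLY instead of binary little-endian.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path, text=ply_text)
    else:
        _write_las(cloud, path)
    return path
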