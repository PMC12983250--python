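"""Point cloud and mesh file I/O: PLY (ascii and binary little-endian)
with uchar label channels, and OBJ meshes.

Coordinates are stored as float32 ``x,y,z`` vertex properties; label
channels (``organ``, ``visibility``) as uchar.  Writers are atomic (write
to a temp file, then rename).  Readers fail loudly: a malformed header or
truncated payload raises ``PlyParseError`` naming the byte offset.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("u1", 1), "uint8": ("u1", 1),
    "char": ("i1", 1), "int8": ("i1", 1),
    "short": ("<i2", 2), "ushort": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


class PlyParseError(ValueError):
    pass


def _atomic_write(path: Path, payload: bytes):
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_point_cloud(path, points: np.ndarray,
                      labels: dict[str, np.ndarray] | None = None,
                      binary: bool = True, comments: list[str] | None = None):
    """Write a PLY cloud with optional uchar label channels."""
    points = np.asarray(points, dtype=np.float32)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    labels = labels or {}
    for name, arr in labels.items():
        if len(arr) != len(points):
            raise ValueError(f"label channel {name!r} length mismatch")

    fmt = "binary_little_endian" if binary else "ascii"
    header = [f"ply", f"format {fmt} 1.0"]
    for c in comments or []:
        header.append(f"comment {c}")
    header.append(f"element vertex {len(points)}")
    header += ["property float x", "property float y", "property float z"]
    for name in labels:
        header.append(f"property uchar {name}")
    header.append("end_header")

    if binary:
        dtype = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
        dtype += [(name, "u1") for name in labels]
        rec = np.empty(len(points), dtype=dtype)
        rec["x"], rec["y"], rec["z"] = points.T
        for name, arr in labels.items():
            rec[name] = np.asarray(arr, dtype=np.uint8)
        payload = ("\n".join(header) + "\n").encode() + rec.tobytes()
    else:
        lines = []
        label_cols = [np.asarray(a, dtype=np.uint8) for a in labels.values()]
        for i, p in enumerate(points):
            row = f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            for col in label_cols:
                row += f" {int(col[i])}"
            lines.append(row)
        payload = ("\n".join(header) + "\n" + "\n".join(lines) + "\n").encode()
    _atomic_write(Path(path), payload)


def read_point_cloud(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a PLY cloud; returns (points, label channels).

    Supports ascii and binary_little_endian vertex elements with float or
    double coordinates; non-coordinate properties are returned in the
    label dict with their native dtype.
    """
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise PlyParseError(f"{path}: not a PLY file (no header terminator; "
                            f"searched {len(raw)} bytes)")
    header_len = raw.index(b"\n", end) + 1
    header = raw[:header_len].decode("ascii", errors="replace").splitlines()

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyParseError(f"{path}: list properties on vertices unsupported")
            if tok[1] not in _PLY_TYPES:
                raise PlyParseError(f"{path}: unknown property type {tok[1]!r}")
            props.append((tok[2], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyParseError(f"{path}: unsupported format {fmt!r}")
    if n_vertex is None:
        raise PlyParseError(f"{path}: missing vertex element in header")

    names = [name for name, _ in props]
    if fmt == "ascii":
        text = raw[header_len:].decode("ascii", errors="replace").split()
        expected = n_vertex * len(props)
        if len(text) < expected:
            raise PlyParseError(
                f"{path}: truncated ascii payload at byte {len(raw)}: "
                f"expected {expected} values, found {len(text)}")
        table = np.array(text[:expected], dtype=float).reshape(n_vertex, len(props))
        columns = {name: table[:, i] for i, (name, _) in enumerate(props)}
        for i, (name, typ) in enumerate(props):
            columns[name] = table[:, i].astype(np.dtype(_PLY_TYPES[typ][0]))
    else:
        dtype = np.dtype([(name, _PLY_TYPES[typ][0]) for name, typ in props])
        expected = n_vertex * dtype.itemsize
        body = raw[header_len:header_len + expected]
        if len(body) < expected:
            raise PlyParseError(
                f"{path}: truncated binary payload at byte {header_len + len(body)}: "
                f"expected {expected} payload bytes, found {len(body)}")
        rec = np.frombuffer(body, dtype=dtype)
        columns = {name: np.array(rec[name]) for name in names}

    for coord in ("x", "y", "z"):
        if coord not in columns:
            raise PlyParseError(f"{path}: missing coordinate property {coord!r}")
    points = np.column_stack([columns["x"], columns["y"], columns["z"]]).astype(np.float32)
    labels = {k: v for k, v in columns.items() if k not in ("x", "y", "z")}
    return points, labels


def write_mesh_obj(path, vertices: np.ndarray, triangles: np.ndarray):
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    lines = [f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for v in vertices]
    lines += [f"f {t[0]+1} {t[1]+1} {t[2]+1}" for t in triangles]
    _atomic_write(Path(path), ("\n".join(lines) + "\n").encode())


def read_mesh_obj(path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "v":
            if len(tok) < 4:
                raise ValueError(f"{path}:{ln}: malformed vertex line")
            verts.append([float(x) for x in tok[1:4]])
        elif tok[0] == "f":
            if len(tok) < 4:
                raise ValueError(f"{path}:{ln}: malformed face line")
            face = [int(t.split("/")[0]) - 1 for t in tok[1:4]]
            faces.append(face)
    return (np.asarray(verts, dtype=float),
            np.asarray(faces, dtype=np.int64).reshape(-1, 3))
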