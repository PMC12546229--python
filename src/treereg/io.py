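"""Point-cloud file I/O: PLY (ascii / binary little-endian), PCD, XYZ text.

Only the subset of each format that TLS tree scans actually use is supported:
an element/field set containing float ``x y z`` plus optional integer scalar
fields ``label`` and ``branch_id``. Unknown scalar fields are skipped; list
properties and big-endian PLY are rejected with a clear error. Units are
passed through unchanged (the pipeline works in meters throughout).
"""

from __future__ import annotations

import os

import numpy as np

from .cloud import PointCloud
from .errors import CloudIOError, CloudParseError

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

_PCD_TYPES = {("F", 4): "f4", ("F", 8): "f8",
              ("I", 1): "i1", ("I", 2): "i2", ("I", 4): "i4",
              ("U", 1): "u1", ("U", 2): "u2", ("U", 4): "u4"}


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz", "txt", "asc"):
        return "ply" if ext == "ply" else "pcd" if ext == "pcd" else "xyz"
    raise CloudIOError(f"cannot detect point-cloud format from extension: {path!r}")


def read_cloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud, preserving point order.

    Parameters
    ----------
    path : str
        Input file.
    format : {"auto", "ply", "pcd", "xyz"}
        ``auto`` dispatches on the file extension.
    """
    fmt = _detect_format(path) if format == "auto" else format
    if not os.path.exists(path):
        raise CloudIOError(f"file not found: {path}")
    try:
        if fmt == "ply":
            return _read_ply(path)
        if fmt == "pcd":
            return _read_pcd(path)
        if fmt == "xyz":
            return _read_xyz(path)
    except (CloudParseError, CloudIOError):
        raise
    except OSError as exc:
        raise CloudIOError(f"cannot read {path}: {exc}") from exc
    raise CloudIOError(f"unknown format {format!r}")


def write_cloud(cloud: PointCloud, path: str, format: str = "auto",
                binary: bool = True) -> None:
    """Write a point cloud; ``label``/``branch_id`` fields are emitted when present.

    Binary dialects store float64 coordinates, so a write/read round trip is
    bit-exact; ascii uses 17 significant digits (also exact for float64).
    """
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "ply":
            _write_ply(cloud, path, binary=binary)
        elif fmt == "pcd":
            _write_pcd(cloud, path, binary=binary)
        elif fmt == "xyz":
            _write_xyz(cloud, path)
        else:
            raise CloudIOError(f"unknown format {format!r}")
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------- PLY

def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError(f"{path}: header ended without end_header")
            tokens = raw.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                if tokens[1] == "binary_big_endian":
                    raise CloudParseError(
                        f"{path}: big-endian PLY is not supported "
                        "(convert to ascii or binary_little_endian)")
                if tokens[1] not in ("ascii", "binary_little_endian"):
                    raise CloudParseError(f"{path}:{lineno}: unknown PLY format {tokens[1]!r}")
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise CloudParseError(f"{path}:{lineno}: property before any element")
                if tokens[1] == "list":
                    elements[-1][2].append(("list:" + tokens[2] + ":" + tokens[3], tokens[4]))
                else:
                    if tokens[1] not in _PLY_TYPES:
                        raise CloudParseError(f"{path}:{lineno}: unknown PLY type {tokens[1]!r}")
                    elements[-1][2].append((_PLY_TYPES[tokens[1]], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt is None:
            raise CloudParseError(f"{path}: PLY header has no format line")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise CloudParseError(f"{path}: PLY has no 'vertex' element")
        if elements.index(vertex) != 0:
            raise CloudParseError(f"{path}: elements before 'vertex' are not supported")
        _, count, props = vertex
        if any(t.startswith("list:") for t, _ in props):
            raise CloudParseError(f"{path}: list properties on 'vertex' are not supported")
        names = [n for _, n in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudParseError(f"{path}: vertex element lacks property {axis!r}")
        if fmt == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline()
                if not line:
                    raise CloudParseError(
                        f"{path}: expected {count} vertex records, file ended after {i}")
                vals = line.split()
                if len(vals) < len(props):
                    raise CloudParseError(
                        f"{path}: vertex record {i} has {len(vals)} values, "
                        f"expected {len(props)}")
                rows.append([float(v) for v in vals[: len(props)]])
            data = {n: np.array([r[j] for r in rows]) for j, (_, n) in enumerate(props)}
        else:
            dtype = np.dtype([(n, "<" + t) for t, n in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) != dtype.itemsize * count:
                raise CloudParseError(
                    f"{path}: expected {count} binary vertex records "
                    f"({dtype.itemsize * count} bytes), got {len(buf)} bytes")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {n: rec[n] for _, n in props}
    return _assemble(data)


def _write_ply(cloud: PointCloud, path: str, binary: bool) -> None:
    props = [("double", "x"), ("double", "y"), ("double", "z")]
    cols: list[np.ndarray] = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.labels is not None:
        props.append(("int", "label"))
        cols.append(cloud.labels)
    if cloud.branch_id is not None:
        props.append(("int", "branch_id"))
        cols.append(cloud.branch_id)
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for t, n in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(n, "<" + _PLY_TYPES[t]) for t, n in props])
            rec = np.empty(len(cloud), dtype=dtype)
            for (t, n), col in zip(props, cols):
                rec[n] = col
            fh.write(rec.tobytes())
        else:
            for i in range(len(cloud)):
                parts = []
                for (t, _), col in zip(props, cols):
                    parts.append(f"{col[i]:.17g}" if t == "double" else str(int(col[i])))
                fh.write((" ".join(parts) + "\n").encode("ascii"))


# ---------------------------------------------------------------- PCD

def _read_pcd(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        lineno = 0
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError(f"{path}: PCD header ended before DATA line")
            tokens = raw.decode("ascii", "replace").split()
            if not tokens or tokens[0].startswith("#"):
                continue
            header[tokens[0].upper()] = tokens[1:]
            if tokens[0].upper() == "DATA":
                break
        for key in ("FIELDS", "SIZE", "TYPE", "POINTS", "DATA"):
            if key not in header:
                raise CloudParseError(f"{path}: PCD header missing {key}")
        fields = header["FIELDS"]
        sizes = [int(s) for s in header["SIZE"]]
        types = header["TYPE"]
        counts = [int(c) for c in header.get("COUNT", ["1"] * len(fields))]
        if any(c != 1 for c in counts):
            raise CloudParseError(f"{path}: PCD COUNT != 1 not supported")
        n = int(header["POINTS"][0])
        mode = header["DATA"][0].lower()
        np_types = []
        for f, t, s in zip(fields, types, sizes):
            if (t, s) not in _PCD_TYPES:
                raise CloudParseError(f"{path}: unsupported PCD field type {t}{s} for {f!r}")
            np_types.append(_PCD_TYPES[(t, s)])
        for axis in ("x", "y", "z"):
            if axis not in fields:
                raise CloudParseError(f"{path}: PCD FIELDS lack {axis!r}")
        if mode == "ascii":
            rows = []
            for i in range(n):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise CloudParseError(
                        f"{path}: expected {n} PCD records, file ended after {i}")
                vals = line.split()
                if len(vals) < len(fields):
                    raise CloudParseError(
                        f"{path}:{lineno}: record has {len(vals)} values, "
                        f"expected {len(fields)}")
                rows.append([float(v) for v in vals[: len(fields)]])
            data = {f: np.array([r[j] for r in rows]) for j, f in enumerate(fields)}
        elif mode == "binary":
            dtype = np.dtype([(f, "<" + t) for f, t in zip(fields, np_types)])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) != dtype.itemsize * n:
                raise CloudParseError(
                    f"{path}: expected {dtype.itemsize * n} bytes of PCD data, "
                    f"got {len(buf)}")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {f: rec[f] for f in fields}
        else:
            raise CloudParseError(f"{path}: PCD DATA mode {mode!r} not supported")
    return _assemble(data)


def _write_pcd(cloud: PointCloud, path: str, binary: bool) -> None:
    fields = ["x", "y", "z"]
    types = ["F", "F", "F"]
    sizes = [8, 8, 8]
    cols = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.labels is not None:
        fields.append("label"); types.append("I"); sizes.append(4)
        cols.append(cloud.labels)
    if cloud.branch_id is not None:
        fields.append("branch_id"); types.append("I"); sizes.append(4)
        cols.append(cloud.branch_id)
    n = len(cloud)
    header = ["# .PCD v0.7 - Point Cloud Data file format",
              "VERSION 0.7",
              "FIELDS " + " ".join(fields),
              "SIZE " + " ".join(str(s) for s in sizes),
              "TYPE " + " ".join(types),
              "COUNT " + " ".join("1" for _ in fields),
              f"WIDTH {n}", "HEIGHT 1",
              "VIEWPOINT 0 0 0 1 0 0 0",
              f"POINTS {n}",
              "DATA " + ("binary" if binary else "ascii")]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(f, "<" + _PCD_TYPES[(t, s)])
                              for f, t, s in zip(fields, types, sizes)])
            rec = np.empty(n, dtype=dtype)
            for f, col in zip(fields, cols):
                rec[f] = col
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                parts = [f"{col[i]:.17g}" if t == "F" else str(int(col[i]))
                         for col, t in zip(cols, types)]
                fh.write((" ".join(parts) + "\n").encode("ascii"))


# ---------------------------------------------------------------- XYZ

def _read_xyz(path: str) -> PointCloud:
    pts = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            vals = s.split()
            if len(vals) < 3:
                raise CloudParseError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(vals)}")
            try:
                pts.append((float(vals[0]), float(vals[1]), float(vals[2])))
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from exc
    return PointCloud(np.array(pts, dtype=np.float64).reshape(-1, 3))


def _write_xyz(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        for p in cloud.points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def _assemble(data: dict[str, np.ndarray]) -> PointCloud:
    pts = np.column_stack([np.asarray(data["x"], dtype=np.float64),
                           np.asarray(data["y"], dtype=np.float64),
                           np.asarray(data["z"], dtype=np.float64)])
    labels = np.asarray(data["label"], dtype=np.int32) if "label" in data else None
    bid = np.asarray(data["branch_id"], dtype=np.int32) if "branch_id" in data else None
    return PointCloud(pts, labels=labels, branch_id=bid)
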