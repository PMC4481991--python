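"""Point-cloud file I/O: PLY (ASCII / binary little-endian) and XYZ text.

PLY is the canonical interchange format.  Besides ``x y z`` (and optional
``red green blue``) the writer emits the extra integer vertex properties
``label`` (organ id) and ``artifact`` (0/1 false-point flag) when the cloud
carries those channels, so a single file keeps full provenance for
evaluation.  ASCII files store coordinates at float64 precision, binary
files at float32.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .cloud import PointCloud, UnitState

__all__ = ["read_cloud", "write_cloud", "read_ply", "write_ply",
           "read_xyz", "write_xyz", "PlyParseError"]


class PlyParseError(ValueError):
    """Malformed PLY/XYZ input; message carries line/element context."""


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


def read_cloud(path: str, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud; ``format`` is ``"ply"``/``"xyz"`` or inferred from suffix."""
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "ply":
        return read_ply(path)
    if format in ("xyz", "txt"):
        return read_xyz(path)
    raise ValueError(f"unknown point-cloud format: {format!r}")


def write_cloud(cloud: PointCloud, path: str, format: Optional[str] = None,
                binary: bool = False) -> None:
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "ply":
        write_ply(cloud, path, binary=binary)
    elif format in ("xyz", "txt"):
        write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format: {format!r}")


def write_ply(cloud: PointCloud, path: str, binary: bool = False) -> None:
    coord_type = "float" if binary else "double"
    lines = [
        "ply",
        "format binary_little_endian 1.0" if binary else "format ascii 1.0",
        "comment written by phyto3d",
        f"comment unit_state {cloud.unit_state.value}",
        f"element vertex {cloud.n}",
        f"property {coord_type} x",
        f"property {coord_type} y",
        f"property {coord_type} z",
    ]
    if cloud.colors is not None:
        lines += ["property uchar red", "property uchar green", "property uchar blue"]
    if cloud.labels is not None:
        lines.append("property int label")
    if cloud.artifact_flags is not None:
        lines.append("property uchar artifact")
    lines.append("end_header")
    header = "\n".join(lines) + "\n"

    fields = [("x", "f4" if binary else "f8"),
              ("y", "f4" if binary else "f8"),
              ("z", "f4" if binary else "f8")]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    if cloud.labels is not None:
        fields.append(("label", "i4"))
    if cloud.artifact_flags is not None:
        fields.append(("artifact", "u1"))
    rec = np.zeros(cloud.n, dtype=[(name, "<" + t) for name, t in fields])
    rec["x"], rec["y"], rec["z"] = cloud.coordinates.T
    if cloud.colors is not None:
        rec["red"], rec["green"], rec["blue"] = cloud.colors.T
    if cloud.labels is not None:
        rec["label"] = cloud.labels
    if cloud.artifact_flags is not None:
        rec["artifact"] = cloud.artifact_flags.astype(np.uint8)

    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for row in rec:
                parts = [repr(float(row["x"])), repr(float(row["y"])), repr(float(row["z"]))]
                for name, t in fields[3:]:
                    parts.append(str(int(row[name])))
                fh.write(" ".join(parts) + "\n")


def read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        data = fh.read()
    # Header is ASCII up to "end_header".
    marker = b"end_header"
    idx = data.find(marker)
    if idx < 0:
        raise PlyParseError(f"{path}: no end_header found")
    header_text = data[:idx].decode("ascii", errors="replace")
    body_start = idx + len(marker)
    # consume a single newline after end_header
    if data[body_start:body_start + 2] == b"\r\n":
        body_start += 2
    elif data[body_start:body_start + 1] == b"\n":
        body_start += 1

    fmt = None
    n_vertices = None
    props: list[tuple[str, str]] = []  # (name, numpy dtype code)
    unit_state = UnitState.ARBITRARY
    current_element = None
    for lineno, raw in enumerate(header_text.splitlines(), start=1):
        tok = raw.strip().split()
        if not tok:
            continue
        if lineno == 1 and tok[0] != "ply":
            raise PlyParseError(f"{path}:1: not a PLY file (missing 'ply' magic)")
        if tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise PlyParseError(f"{path}:{lineno}: unsupported PLY format {tok[1]!r}")
            fmt = tok[1]
        elif tok[0] == "comment":
            if len(tok) >= 3 and tok[1] == "unit_state":
                try:
                    unit_state = UnitState(tok[2])
                except ValueError:
                    pass
        elif tok[0] == "element":
            current_element = tok[1]
            if tok[1] == "vertex":
                n_vertices = int(tok[2])
            elif int(tok[2]) != 0:
                raise PlyParseError(
                    f"{path}:{lineno}: unsupported non-empty element {tok[1]!r}"
                )
        elif tok[0] == "property" and current_element == "vertex":
            if tok[1] == "list":
                raise PlyParseError(f"{path}:{lineno}: list properties unsupported on vertices")
            if tok[1] not in _PLY_TYPES:
                raise PlyParseError(f"{path}:{lineno}: unknown property type {tok[1]!r}")
            props.append((tok[2], _PLY_TYPES[tok[1]]))
    if fmt is None or n_vertices is None:
        raise PlyParseError(f"{path}: header lacks format or vertex element")
    names = [p[0] for p in props]
    for required in ("x", "y", "z"):
        if required not in names:
            raise PlyParseError(f"{path}: vertex element lacks property {required!r}")

    dtype = np.dtype([(name, "<" + code) for name, code in props])
    if fmt == "binary_little_endian":
        expected = n_vertices * dtype.itemsize
        body = data[body_start:body_start + expected]
        if len(body) < expected:
            raise PlyParseError(
                f"{path}: vertex element declares {n_vertices} vertices but body holds "
                f"only {len(body) // max(dtype.itemsize, 1)}"
            )
        rec = np.frombuffer(body, dtype=dtype, count=n_vertices)
    else:
        text = data[body_start:].decode("ascii", errors="replace")
        rows = [ln.split() for ln in text.splitlines() if ln.strip()]
        if len(rows) < n_vertices:
            raise PlyParseError(
                f"{path}: vertex element declares {n_vertices} vertices but body holds "
                f"only {len(rows)}"
            )
        rec = np.zeros(n_vertices, dtype=dtype)
        for i in range(n_vertices):
            row = rows[i]
            if len(row) != len(props):
                raise PlyParseError(
                    f"{path}: vertex {i}: expected {len(props)} values, got {len(row)}"
                )
            for (name, code), value in zip(props, row):
                try:
                    rec[name][i] = float(value) if code.startswith("f") else int(float(value))
                except ValueError as exc:
                    raise PlyParseError(f"{path}: vertex {i}: bad value {value!r}") from exc

    coords = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.stack([rec["red"], rec["green"], rec["blue"]], axis=1).astype(np.uint8)
    labels = rec["label"].astype(np.int32) if "label" in names else None
    flags = rec["artifact"].astype(bool) if "artifact" in names else None
    return PointCloud(coords, colors=colors, labels=labels, artifact_flags=flags,
                      unit_state=unit_state)


def read_xyz(path: str) -> PointCloud:
    """Whitespace-delimited ``x y z`` or ``x y z r g b`` rows."""
    coords = []
    colors = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if n_cols is None:
                if len(tok) not in (3, 6):
                    raise PlyParseError(
                        f"{path}:{lineno}: expected 3 (xyz) or 6 (xyzrgb) columns, got {len(tok)}"
                    )
                n_cols = len(tok)
            if len(tok) != n_cols:
                raise PlyParseError(
                    f"{path}:{lineno}: inconsistent column count {len(tok)} (expected {n_cols})"
                )
            try:
                values = [float(v) for v in tok]
            except ValueError as exc:
                raise PlyParseError(f"{path}:{lineno}: non-numeric value") from exc
            coords.append(values[:3])
            if n_cols == 6:
                colors.append(values[3:])
    coords_arr = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    colors_arr = (
        np.asarray(colors, dtype=np.float64).round().astype(np.uint8)
        if colors else None
    )
    return PointCloud(coords_arr, colors=colors_arr)


def write_xyz(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        for i in range(cloud.n):
            x, y, z = (float(v) for v in cloud.coordinates[i])
            row = f"{x!r} {y!r} {z!r}"
            if cloud.colors is not None:
                r, g, b = cloud.colors[i]
                row += f" {int(r)} {int(g)} {int(b)}"
            fh.write(row + "\n")
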