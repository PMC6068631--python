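"""File I/O: PLY point clouds and the CSV side formats.

The PLY support covers the two dialects dense-reconstruction tools emit:
``ascii 1.0`` and ``binary_little_endian 1.0``, with float/double vertex
coordinates and optional 8-bit red/green/blue properties.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .exceptions import FormatError
from .objects import RectRegion

__all__ = ["read_ply", "write_ply", "read_truth_csv", "read_regions_csv"]

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


def _parse_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Returns (format, vertex count, [(name, dtype)], header byte length)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise FormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        line = fh.readline()
        if not line:
            raise FormatError("unexpected end of PLY header")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
            elif n_vertex is None:
                raise FormatError("only PLY files whose first element is 'vertex' are supported")
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise FormatError("list properties are not supported on vertices")
            if tokens[1] not in _PLY_TYPES:
                raise FormatError(f"unsupported PLY property type {tokens[1]!r}")
            props.append((tokens[2], _PLY_TYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise FormatError("PLY file has no vertex element")
    for needed in ("x", "y", "z"):
        if needed not in [p[0] for p in props]:
            raise FormatError(f"PLY vertex element is missing property {needed!r}")
    return fmt, n_vertex, props, fh.tell()


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY file into a PointCloud (colors kept when present)."""
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, n_vertex, props, offset = _parse_header(fh)
        names = [p[0] for p in props]
        if fmt == "binary_little_endian":
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            data = np.fromfile(fh, dtype=dtype, count=n_vertex)
            if len(data) != n_vertex:
                raise FormatError(f"expected {n_vertex} vertices, file holds {len(data)}")
        else:
            raw = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
            if raw.shape != (n_vertex, len(props)):
                raise FormatError(
                    f"expected {n_vertex} x {len(props)} ASCII values, got {raw.shape}"
                )
            data = np.rec.fromarrays(list(raw.T), names=names)
    xyz = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    rgb = None
    if all(c in names for c in ("red", "green", "blue")):
        rgb = np.column_stack([data["red"], data["green"], data["blue"]]).astype(np.uint8)
    return PointCloud(xyz, rgb)


def write_ply(path: str | Path, cloud: PointCloud, binary: bool = False) -> None:
    """Write a PointCloud as PLY (float32 coordinates, uchar colors)."""
    path = Path(path)
    n = len(cloud)
    header = ["ply"]
    header.append(f"format {'binary_little_endian' if binary else 'ascii'} 1.0")
    header.append(f"element vertex {n}")
    header += ["property float x", "property float y", "property float z"]
    if cloud.has_color:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")

    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if cloud.has_color:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    rec = np.empty(n, dtype=np.dtype(fields))
    rec["x"], rec["y"], rec["z"] = cloud.xyz.T.astype(np.float32)
    if cloud.has_color:
        rec["red"], rec["green"], rec["blue"] = cloud.rgb.T

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec.tofile(fh)
        else:
            for row in rec:
                coords = " ".join(f"{float(row[c]):.6f}" for c in ("x", "y", "z"))
                if cloud.has_color:
                    coords += " " + " ".join(
                        str(int(row[c])) for c in ("red", "green", "blue")
                    )
                fh.write((coords + "\n").encode("ascii"))


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    """Ground-truth dimensions; replicate rows per object are averaged.

    Required columns: ``object_id``, ``dim_x``, ``dim_y``, ``dim_z`` (mm).
    Repeated manual measurements appear as repeated rows and are reduced to
    their per-object mean.
    """
    df = pd.read_csv(path)
    required = ["object_id", "dim_x", "dim_y", "dim_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in ("dim_x", "dim_y", "dim_z"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0]) + 2}"
            )
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0]) + 2
            raise FormatError(f"{path}: empty value in column {col!r} at row {row}")
        df[col] = numeric
    return df.groupby("object_id", as_index=False)[["dim_x", "dim_y", "dim_z"]].mean()


def read_regions_csv(path: str | Path) -> "dict[str, RectRegion]":
    """Crop rectangles keyed by object id.

    Required columns: ``object_id``, ``x_min``, ``x_max``, ``y_min``, ``y_max``.
    """
    df = pd.read_csv(path)
    required = ["object_id", "x_min", "x_max", "y_min", "y_max"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    regions = {}
    for _, row in df.iterrows():
        regions[str(row["object_id"])] = RectRegion(
            float(row["x_min"]), float(row["x_max"]),
            float(row["y_min"]), float(row["y_max"]),
        )
    return regions
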