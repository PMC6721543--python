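"""Point-cloud file I/O: ASCII PLY, PCD (v0.7) and XYZ text formats.

All three are plain-text formats; coordinates are written with 6 decimal
places and round-trip to that precision. Binary PLY/PCD dialects are
rejected explicitly.
"""

from __future__ import annotations

import os

import numpy as np

from .core import PointCloud

FORMATS = ("ply", "pcd", "xyz")


class ParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown point-cloud format {fmt!r}; "
                         f"expected one of {FORMATS}")
    return fmt


def read_cloud(path: str, fmt: str | None = None) -> PointCloud:
    """Load a cloud; the format defaults to the file extension."""
    fmt = _detect_format(path, fmt)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if fmt == "ply":
        return _read_ply(path, lines)
    if fmt == "pcd":
        return _read_pcd(path, lines)
    return _read_xyz(path, lines)


def write_cloud(cloud: PointCloud, path: str, fmt: str | None = None) -> None:
    """Write a cloud (normals included when present) as text."""
    fmt = _detect_format(path, fmt)
    with open(path, "w") as fh:
        if fmt == "ply":
            _write_ply(cloud, fh)
        elif fmt == "pcd":
            _write_pcd(cloud, fh)
        else:
            _write_xyz(cloud, fh)


def _parse_rows(path, lines, start_no, n_rows, n_cols):
    rows = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        line_no = start_no + i
        if line_no > len(lines):
            raise ParseError(path, line_no, "unexpected end of file")
        fields = lines[line_no - 1].split()
        if len(fields) < n_cols:
            raise ParseError(path, line_no,
                             f"expected {n_cols} values, got {len(fields)}")
        try:
            rows[i] = [float(v) for v in fields[:n_cols]]
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from None
    return rows


# -- PLY --------------------------------------------------------------------

def _read_ply(path, lines):
    if not lines or lines[0].strip() != "ply":
        raise ParseError(path, 1, "missing 'ply' magic")
    n_vertices = None
    properties: list[str] = []
    in_vertex_element = False
    header_end = None
    for i, raw in enumerate(lines[1:], start=2):
        tokens = raw.split()
        if not tokens:
            continue
        if tokens[0] == "format":
            if tokens[1] != "ascii":
                raise ValueError(
                    f"{path}: unsupported dialect: binary PLY not supported")
        elif tokens[0] == "element":
            in_vertex_element = tokens[1] == "vertex"
            if in_vertex_element:
                n_vertices = int(tokens[2])
        elif tokens[0] == "property" and in_vertex_element:
            properties.append(tokens[-1])
        elif tokens[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vertices is None:
        raise ParseError(path, len(lines), "incomplete PLY header")
    for name in ("x", "y", "z"):
        if name not in properties:
            raise ParseError(path, header_end, f"missing property {name!r}")
    data = _parse_rows(path, lines, header_end + 1, n_vertices,
                       len(properties))
    cols = {name: data[:, j] for j, name in enumerate(properties)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(n in cols for n in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(points=points, normals=normals)


def _write_ply(cloud, fh):
    has_normals = cloud.normals is not None
    fh.write("ply\nformat ascii 1.0\n")
    fh.write(f"element vertex {len(cloud)}\n")
    fh.write("property float x\nproperty float y\nproperty float z\n")
    if has_normals:
        fh.write("property float nx\nproperty float ny\nproperty float nz\n")
    fh.write("end_header\n")
    for i in range(len(cloud)):
        row = list(cloud.points[i])
        if has_normals:
            row += list(cloud.normals[i])
        fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# -- PCD --------------------------------------------------------------------

def _read_pcd(path, lines):
    fields = None
    n_points = None
    data_start = None
    for i, raw in enumerate(lines, start=1):
        tokens = raw.split()
        if not tokens or tokens[0] == "#":
            continue
        key = tokens[0].upper()
        if key == "FIELDS":
            fields = tokens[1:]
        elif key == "POINTS":
            n_points = int(tokens[1])
        elif key == "DATA":
            if tokens[1] != "ascii":
                raise ValueError(
                    f"{path}: unsupported dialect: binary PCD not supported")
            data_start = i + 1
            break
    if fields is None or n_points is None or data_start is None:
        raise ParseError(path, len(lines), "incomplete PCD header")
    for name in ("x", "y", "z"):
        if name not in fields:
            raise ParseError(path, data_start - 1, f"missing field {name!r}")
    data = _parse_rows(path, lines, data_start, n_points, len(fields))
    cols = {name: data[:, j] for j, name in enumerate(fields)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(n in cols for n in ("normal_x", "normal_y", "normal_z")):
        normals = np.column_stack(
            [cols["normal_x"], cols["normal_y"], cols["normal_z"]])
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(points=points, normals=normals)


def _write_pcd(cloud, fh):
    has_normals = cloud.normals is not None
    names = ["x", "y", "z"]
    if has_normals:
        names += ["normal_x", "normal_y", "normal_z"]
    n = len(names)
    fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
    fh.write("VERSION 0.7\n")
    fh.write("FIELDS " + " ".join(names) + "\n")
    fh.write("SIZE " + " ".join(["4"] * n) + "\n")
    fh.write("TYPE " + " ".join(["F"] * n) + "\n")
    fh.write("COUNT " + " ".join(["1"] * n) + "\n")
    fh.write(f"WIDTH {len(cloud)}\nHEIGHT 1\n")
    fh.write("VIEWPOINT 0 0 0 1 0 0 0\n")
    fh.write(f"POINTS {len(cloud)}\nDATA ascii\n")
    for i in range(len(cloud)):
        row = list(cloud.points[i])
        if has_normals:
            row += list(cloud.normals[i])
        fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# -- XYZ --------------------------------------------------------------------

def _read_xyz(path, lines):
    rows = []
    width = None
    for i, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split()
        if width is None:
            width = 6 if len(fields) >= 6 else 3
        if len(fields) < width:
            raise ParseError(path, i, f"expected {width} values, "
                                      f"got {len(fields)}")
        try:
            rows.append([float(v) for v in fields[:width]])
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from None
    if not rows:
        raise ParseError(path, 1, "no data rows")
    data = np.asarray(rows)
    normals = None
    if data.shape[1] == 6:
        normals = data[:, 3:6]
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return PointCloud(points=data[:, :3], normals=normals)


def _write_xyz(cloud, fh):
    has_normals = cloud.normals is not None
    for i in range(len(cloud)):
        row = list(cloud.points[i])
        if has_normals:
            row += list(cloud.normals[i])
        fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
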