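"""Point-cloud and mesh file I/O plus configuration parsing.

Supported cloud formats:

* PLY — ``ascii`` and ``binary_little_endian``; vertex properties x,y,z
  (float), optional normal_x/normal_y/normal_z and an optional uchar
  ``gt_label`` scalar carrying the ground-truth class.
* PCD — ``ascii`` and ``binary``; FIELDS x y z [normal_x normal_y normal_z]
  [gt_label].

Meshes export as PLY (vertex + face elements) or OFF.  Lengths in config
files may carry a unit tag (m / cm / mm) and are converted to metres.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .core import CameraModel, LabeledCloud, RigidTransform
from .errors import InvalidInputError

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_ply",
    "write_ply",
    "read_pcd",
    "write_pcd",
    "write_mesh_ply",
    "write_mesh_off",
    "parse_length",
    "load_camera",
    "load_config",
]

_UNIT_SCALE = {"m": 1.0, "cm": 0.01, "mm": 0.001}

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def parse_length(value: Union[str, float, int], default_unit: str = "m") -> float:
    """Parse a length with an optional unit suffix ('3.5cm', '2 mm') to metres."""
    if isinstance(value, (int, float)):
        return float(value) * _UNIT_SCALE[default_unit]
    s = str(value).strip().lower()
    for unit in ("mm", "cm", "m"):
        if s.endswith(unit):
            return float(s[: -len(unit)].strip()) * _UNIT_SCALE[unit]
    return float(s) * _UNIT_SCALE[default_unit]


# ---------------------------------------------------------------------------
# PLY

def write_ply(path, cloud: LabeledCloud, binary: bool = True) -> None:
    path = Path(path)
    n = len(cloud)
    props = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    cols = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.normals is not None:
        props += [("nx", "<f8"), ("ny", "<f8"), ("nz", "<f8")]
        cols += [cloud.normals[:, 0], cloud.normals[:, 1], cloud.normals[:, 2]]
    if cloud.labels is not None:
        props += [("gt_label", "u1")]
        cols += [cloud.labels.astype(np.uint8)]

    names = {"nx": "normal_x", "ny": "normal_y", "nz": "normal_z"}
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}"]
    for name, dt in props:
        ply_t = "double" if dt == "<f8" else "uchar"
        header.append(f"property {ply_t} {names.get(name, name)}")
    header.append("end_header")

    rec = np.rec.fromarrays(cols, dtype=props) if cols else np.empty(0)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            fmt = " ".join("%d" if dt == "u1" else "%.10g" for _, dt in props)
            for row in rec:
                fh.write((fmt % tuple(row) + "\n").encode("ascii"))


def _read_ply_header(fh):
    line = fh.readline().decode("ascii").strip()
    if line != "ply":
        raise InvalidInputError("not a PLY file")
    fmt = None
    elements = []  # (name, count, [(prop_name, dtype)])
    while True:
        line = fh.readline().decode("ascii").strip()
        if not line or line.startswith("comment"):
            continue
        if line == "end_header":
            break
        tok = line.split()
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if tok[1] == "list":
                elements[-1][2].append((tok[-1], ("list", _PLY_DTYPES[tok[2]], _PLY_DTYPES[tok[3]])))
            else:
                elements[-1][2].append((tok[2], _PLY_DTYPES[tok[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise InvalidInputError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def read_ply(path) -> LabeledCloud:
    with open(path, "rb") as fh:
        fmt, elements = _read_ply_header(fh)
        data = {}
        for name, count, props in elements:
            if any(isinstance(dt, tuple) for _, dt in props):
                # list properties (faces) — skip for cloud reading
                if fmt == "ascii":
                    for _ in range(count):
                        fh.readline()
                else:
                    for _ in range(count):
                        for _, dt in props:
                            if isinstance(dt, tuple):
                                cnt_dt, item_dt = np.dtype(dt[1]), np.dtype(dt[2])
                                (m,) = struct.unpack("<" + {1: "B", 2: "H", 4: "I"}[cnt_dt.itemsize],
                                                     fh.read(cnt_dt.itemsize))
                                fh.read(item_dt.itemsize * m)
                            else:
                                fh.read(np.dtype(dt).itemsize)
                continue
            dtype = np.dtype([(p, dt) for p, dt in props])
            if fmt == "ascii":
                rows = [fh.readline().split() for _ in range(count)]
                arr = np.zeros(count, dtype=dtype)
                for j, (p, _) in enumerate(props):
                    arr[p] = np.array([r[j] for r in rows], dtype=dtype[p])
            else:
                arr = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
            data[name] = arr

    if "vertex" not in data:
        raise InvalidInputError("PLY file has no vertex element")
    v = data["vertex"]
    pts = np.stack([v["x"], v["y"], v["z"]], axis=1).astype(np.float64)
    normals = None
    if all(f in v.dtype.names for f in ("normal_x", "normal_y", "normal_z")):
        normals = np.stack([v["normal_x"], v["normal_y"], v["normal_z"]], axis=1).astype(np.float64)
        # re-normalize: float32 storage loses the unit-length invariant
        norm = np.linalg.norm(normals, axis=1)
        ok = norm > 0
        normals[ok] /= norm[ok][:, None]
        normals[~ok] = np.nan
    labels = np.asarray(v["gt_label"], dtype=np.int16) if "gt_label" in v.dtype.names else None
    return LabeledCloud(points=pts, normals=normals, labels=labels)


def write_mesh_ply(path, vertices: np.ndarray, faces: np.ndarray, binary: bool = False) -> None:
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(vertices)}",
              "property double x", "property double y", "property double z",
              f"element face {len(faces)}",
              "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(vertices.astype("<f8").tobytes())
            for f in faces:
                fh.write(struct.pack("<B3i", 3, *f))
        else:
            for v in vertices:
                fh.write(("%.10g %.10g %.10g\n" % tuple(v)).encode("ascii"))
            for f in faces:
                fh.write(("3 %d %d %d\n" % tuple(f)).encode("ascii"))


def read_mesh_ply(path):
    """Read vertices and triangular faces from an ascii or binary PLY."""
    with open(path, "rb") as fh:
        fmt, elements = _read_ply_header(fh)
        verts, faces = None, []
        for name, count, props in elements:
            if name == "vertex":
                dtype = np.dtype([(p, dt) for p, dt in props])
                if fmt == "ascii":
                    rows = [fh.readline().split() for _ in range(count)]
                    arr = np.zeros(count, dtype=dtype)
                    for j, (p, _) in enumerate(props):
                        arr[p] = np.array([r[j] for r in rows], dtype=dtype[p])
                else:
                    arr = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
                verts = np.stack([arr["x"], arr["y"], arr["z"]], axis=1).astype(np.float64)
            elif name == "face":
                if fmt == "ascii":
                    for _ in range(count):
                        tok = fh.readline().split()
                        faces.append([int(t) for t in tok[1:1 + int(tok[0])]])
                else:
                    (_, dt) = props[0]
                    cnt_dt, item_dt = np.dtype(dt[1]), np.dtype(dt[2])
                    for _ in range(count):
                        (m,) = struct.unpack("<" + {1: "B", 2: "H", 4: "I"}[cnt_dt.itemsize],
                                             fh.read(cnt_dt.itemsize))
                        faces.append(list(np.frombuffer(fh.read(item_dt.itemsize * m), dtype=item_dt)))
    return verts, np.asarray(faces, dtype=np.int64)


def write_mesh_off(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vertices)} {len(faces)} 0\n")
        for v in vertices:
            fh.write("%.10g %.10g %.10g\n" % tuple(v))
        for f in faces:
            fh.write("3 %d %d %d\n" % tuple(f))


# ---------------------------------------------------------------------------
# PCD

def write_pcd(path, cloud: LabeledCloud, binary: bool = False) -> None:
    fields, sizes, types, counts = ["x", "y", "z"], [4, 4, 4], ["F", "F", "F"], [1, 1, 1]
    cols = [cloud.points[:, i].astype("<f4") for i in range(3)]
    if cloud.normals is not None:
        fields += ["normal_x", "normal_y", "normal_z"]
        sizes += [4, 4, 4]; types += ["F", "F", "F"]; counts += [1, 1, 1]
        cols += [cloud.normals[:, i].astype("<f4") for i in range(3)]
    if cloud.labels is not None:
        fields += ["gt_label"]; sizes += [4]; types += ["U"]; counts += [1]
        cols += [cloud.labels.astype("<u4")]
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {' '.join(fields)}\n"
        f"SIZE {' '.join(map(str, sizes))}\n"
        f"TYPE {' '.join(types)}\n"
        f"COUNT {' '.join(map(str, counts))}\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\n"
        f"DATA {'binary' if binary else 'ascii'}\n"
    )
    dtype = np.dtype([(f, c.dtype) for f, c in zip(fields, cols)])
    rec = np.rec.fromarrays(cols, dtype=dtype)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                fh.write((" ".join(f"{x:.10g}" if isinstance(x, float) or np.issubdtype(type(x), np.floating)
                                   else str(int(x)) for x in row) + "\n").encode("ascii"))


def read_pcd(path) -> LabeledCloud:
    with open(path, "rb") as fh:
        meta = {}
        while True:
            line = fh.readline().decode("ascii", "replace").strip()
            if line.startswith("#") or not line:
                continue
            key, _, rest = line.partition(" ")
            meta[key] = rest.split()
            if key == "DATA":
                break
        fields = meta["FIELDS"]
        sizes = list(map(int, meta["SIZE"]))
        types = meta["TYPE"]
        n = int(meta["POINTS"][0])
        np_types = {("F", 4): "<f4", ("F", 8): "<f8",
                    ("U", 1): "u1", ("U", 2): "<u2", ("U", 4): "<u4",
                    ("I", 1): "i1", ("I", 2): "<i2", ("I", 4): "<i4"}
        dtype = np.dtype([(f, np_types[(t, s)]) for f, t, s in zip(fields, types, sizes)])
        mode = meta["DATA"][0]
        if mode == "ascii":
            rows = [fh.readline().split() for _ in range(n)]
            arr = np.zeros(n, dtype=dtype)
            for j, f in enumerate(fields):
                arr[f] = np.array([r[j] for r in rows], dtype=dtype[f])
        elif mode == "binary":
            arr = np.frombuffer(fh.read(dtype.itemsize * n), dtype=dtype, count=n)
        else:
            raise InvalidInputError(f"unsupported PCD DATA mode {mode!r}")
    pts = np.stack([arr["x"], arr["y"], arr["z"]], axis=1).astype(np.float64)
    normals = None
    if all(f in fields for f in ("normal_x", "normal_y", "normal_z")):
        normals = np.stack([arr["normal_x"], arr["normal_y"], arr["normal_z"]], axis=1).astype(np.float64)
        norm = np.linalg.norm(normals, axis=1)
        ok = norm > 0
        normals[ok] /= norm[ok][:, None]
        normals[~ok] = np.nan
    labels = np.asarray(arr["gt_label"], dtype=np.int16) if "gt_label" in fields else None
    return LabeledCloud(points=pts, normals=normals, labels=labels)


def read_cloud(path) -> LabeledCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply(path)
    if path.suffix.lower() == ".pcd":
        return read_pcd(path)
    raise InvalidInputError(f"unknown cloud format {path.suffix!r}")


def write_cloud(path, cloud: LabeledCloud, binary: bool = False) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        write_ply(path, cloud, binary=binary)
    elif path.suffix.lower() == ".pcd":
        write_pcd(path, cloud, binary=binary)
    else:
        raise InvalidInputError(f"unknown cloud format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Config

def load_camera(source) -> CameraModel:
    """Build a CameraModel from a dict or a YAML/JSON file.

    Keys: ``viewpoint`` (3 lengths), ``tilt_deg`` (degrees), optional
    ``axes`` (3 rows = camera x, y, z directions), optional ``unit``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise InvalidInputError("camera config must be a mapping")
    unit = source.get("unit", "m")
    vp = [parse_length(v, unit) for v in source["viewpoint"]]
    tilt = float(np.deg2rad(source.get("tilt_deg", 0.0)))
    axes = np.asarray(source.get("axes", np.eye(3)), dtype=np.float64)
    if "axes" in source:
        axes = np.asarray(source["axes"], dtype=np.float64).T  # rows in config -> columns
    return CameraModel(viewpoint=vp, tilt_theta=tilt, axes=axes)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def save_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, RigidTransform):
        return {"rotation": o.rotation.tolist(), "translation": o.translation.tolist()}
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
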