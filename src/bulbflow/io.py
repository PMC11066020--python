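"""Readers and writers for the pipeline's on-disk formats.

One dialect per format, written and read by this module only:

* volume mesh (+ optional velocity frames): legacy ASCII VTK unstructured
  grid.  Tetrahedra (cell type 10) carry boundary label 0; the boundary
  triangles (cell type 5) are appended as cells with labels 1=wall,
  2=inlet, 3=outlet_ica, 4=outlet_eca in a ``boundary_label`` CELL_DATA
  array.  Velocity frames are POINT_DATA vector arrays named
  ``velocity_frame_<k>``; the cardiac period is recorded in the title line
  as ``period=<s>``.
* surfaces: ASCII STL plus a CSV label sidecar (triangle_index,label).
* inlet waveform: CSV with header ``time_s,flow_mL_s``.
* subject vitals: YAML with keys systolic_mmHg, diastolic_mmHg,
  heart_rate_bpm, stroke_volume_mL, group, event.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .core import SurfaceMesh, SubjectVitals, VelocityField, VolumeMeshWithBoundary
from .errors import (
    MeshFormatError,
    OrderError,
    SizeError,
    TopologyError,
    UnsupportedCellError,
)

LABEL_CODES = {"wall": 1, "inlet": 2, "outlet_ica": 3, "outlet_eca": 4}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

_FMT = "%.17g"


# ---------------------------------------------------------------------------
# shared geometry helpers

def oriented_face_normals(vertices, tetrahedra, triangles):
    """Outward unit normals for boundary triangles of a tet mesh.

    Each triangle must be a face of exactly one tetrahedron; the normal is
    oriented away from that tetrahedron's remaining vertex.
    """
    tets = np.asarray(tetrahedra)
    tris = np.asarray(triangles)
    nv = len(vertices)
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([np.sort(tets[:, c], axis=1) for c in combos])
    opps = np.concatenate(
        [tets[:, [i for i in range(4) if i not in c]].ravel() for c in combos]
    )

    def encode(f):
        return (f[:, 0].astype(np.int64) * nv + f[:, 1]) * nv + f[:, 2]

    keys = encode(faces)
    order = np.argsort(keys, kind="stable")
    keys_s, opps_s = keys[order], opps[order]
    uniq, start, counts = np.unique(keys_s, return_index=True, return_counts=True)
    bnd = counts == 1
    bkeys, bopps = uniq[bnd], opps_s[start[bnd]]

    qkeys = encode(np.sort(tris, axis=1))
    pos = np.searchsorted(bkeys, qkeys)
    ok = (pos < len(bkeys)) & (bkeys[np.clip(pos, 0, len(bkeys) - 1)] == qkeys)
    if not np.all(ok):
        raise TopologyError("boundary triangle is not a face of any tetrahedron")
    opp_vertex = bopps[pos]

    p = vertices[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise TopologyError("degenerate boundary triangle")
    n = n / norms
    centroids = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", n, centroids - vertices[opp_vertex]) < 0
    n[flip] = -n[flip]
    return n


def build_volume_mesh(vertices, tetrahedra, boundary_tris, boundary_labels,
                      axis_info=None, normals=None):
    """Assemble a VolumeMeshWithBoundary from triangles in volume indexing."""
    vertices = np.asarray(vertices, dtype=float)
    tetrahedra = np.asarray(tetrahedra, dtype=np.int64)
    boundary_tris = np.asarray(boundary_tris, dtype=np.int64)
    if normals is None:
        normals = oriented_face_normals(vertices, tetrahedra, boundary_tris)
    used = np.unique(boundary_tris)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    surface = SurfaceMesh(
        vertices=vertices[used],
        triangles=remap[boundary_tris],
        face_labels=np.asarray(boundary_labels, dtype=object),
        face_normals=normals,
    )
    return VolumeMeshWithBoundary(
        vertices=vertices,
        tetrahedra=tetrahedra,
        boundary=surface,
        boundary_vertex_map=used,
        axis_info=axis_info,
    )


# ---------------------------------------------------------------------------
# legacy VTK dialect

def write_mesh(mesh: VolumeMeshWithBoundary, path, field: VelocityField | None = None):
    """Write mesh (and optional velocity frames) as legacy ASCII VTK."""
    path = Path(path)
    tris = mesh.boundary_triangles_volume_idx
    codes = np.array([LABEL_CODES[l] for l in mesh.boundary.face_labels], dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        title = "bulbflow mesh"
        if field is not None:
            title += f" period={field.period!r} frames={field.n_frames}"
        fh.write(title + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        np.savetxt(fh, mesh.vertices, fmt=_FMT)
        ncells = len(mesh.tetrahedra) + len(tris)
        size = 5 * len(mesh.tetrahedra) + 4 * len(tris)
        fh.write(f"CELLS {ncells} {size}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(mesh.tetrahedra), 4), mesh.tetrahedra]),
            fmt="%d",
        )
        if len(tris):
            np.savetxt(fh, np.column_stack([np.full(len(tris), 3), tris]), fmt="%d")
        fh.write(f"CELL_TYPES {ncells}\n")
        np.savetxt(fh, np.concatenate([np.full(len(mesh.tetrahedra), 10),
                                       np.full(len(tris), 5)])[:, None], fmt="%d")
        fh.write(f"CELL_DATA {ncells}\n")
        fh.write("SCALARS boundary_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.concatenate([np.zeros(len(mesh.tetrahedra), dtype=int),
                                       codes])[:, None], fmt="%d")
        if field is not None:
            fh.write(f"POINT_DATA {len(mesh.vertices)}\n")
            for k in range(field.n_frames):
                fh.write(f"VECTORS velocity_frame_{k} double\n")
                np.savetxt(fh, field.values[k], fmt=_FMT)


def write_field(mesh, field, path):
    write_mesh(mesh, path, field=field)


class _Lines:
    """Line iterator that remembers the current line number for errors."""

    def __init__(self, path):
        with open(path) as fh:
            self.lines = fh.read().splitlines()
        self.i = 0

    def next_nonblank(self):
        while self.i < len(self.lines):
            line = self.lines[self.i]
            self.i += 1
            if line.strip():
                return line
        raise MeshFormatError("unexpected end of file", line=self.i)

    def read_floats(self, n_rows, n_cols, what):
        vals = np.empty((n_rows, n_cols))
        for r in range(n_rows):
            line = self.next_nonblank()
            parts = line.split()
            if len(parts) != n_cols:
                raise MeshFormatError(
                    f"expected {n_cols} values for {what}, got {len(parts)}",
                    line=self.i,
                )
            try:
                vals[r] = [float(p) for p in parts]
            except ValueError:
                raise MeshFormatError(f"non-numeric value in {what}", line=self.i)
        return vals


def _parse_title_meta(title):
    meta = {}
    for tok in title.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            try:
                meta[k] = float(v)
            except ValueError:
                pass
    return meta


def _read_vtk(path):
    lines = _Lines(path)
    header = lines.next_nonblank()
    if not header.startswith("# vtk DataFile"):
        raise MeshFormatError("not a legacy VTK file", line=lines.i)
    title = lines.next_nonblank()
    meta = _parse_title_meta(title)
    if lines.next_nonblank().strip() != "ASCII":
        raise MeshFormatError("only ASCII VTK is supported", line=lines.i)
    if lines.next_nonblank().split() != ["DATASET", "UNSTRUCTURED_GRID"]:
        raise MeshFormatError("only UNSTRUCTURED_GRID is supported", line=lines.i)

    tok = lines.next_nonblank().split()
    if tok[0] != "POINTS":
        raise MeshFormatError("expected POINTS section", line=lines.i)
    npts = int(tok[1])
    points = lines.read_floats(npts, 3, "POINTS")

    tok = lines.next_nonblank().split()
    if tok[0] != "CELLS":
        raise MeshFormatError("expected CELLS section", line=lines.i)
    ncells = int(tok[1])
    conn = []
    for _ in range(ncells):
        parts = lines.next_nonblank().split()
        try:
            row = [int(p) for p in parts]
        except ValueError:
            raise MeshFormatError("non-integer cell connectivity", line=lines.i)
        if not row or len(row) != row[0] + 1:
            raise MeshFormatError("cell connectivity count mismatch", line=lines.i)
        conn.append(row[1:])

    tok = lines.next_nonblank().split()
    if tok[0] != "CELL_TYPES":
        raise MeshFormatError("expected CELL_TYPES section", line=lines.i)
    types = []
    while len(types) < ncells:
        types.extend(int(p) for p in lines.next_nonblank().split())
    types = np.array(types[:ncells])

    labels = None
    frames = {}
    while lines.i < len(lines.lines):
        try:
            tok = lines.next_nonblank().split()
        except MeshFormatError:
            break
        if tok[0] == "CELL_DATA":
            tok = lines.next_nonblank().split()
            if tok[:2] != ["SCALARS", "boundary_label"]:
                raise MeshFormatError("expected SCALARS boundary_label", line=lines.i)
            lines.next_nonblank()  # LOOKUP_TABLE
            vals = []
            while len(vals) < ncells:
                vals.extend(int(p) for p in lines.next_nonblank().split())
            labels = np.array(vals[:ncells])
        elif tok[0] == "POINT_DATA":
            continue
        elif tok[0] == "VECTORS":
            name = tok[1]
            frames[name] = lines.read_floats(npts, 3, name)
        else:
            raise MeshFormatError(f"unexpected section {tok[0]!r}", line=lines.i)

    return points, conn, types, labels, frames, meta


def read_mesh(path) -> VolumeMeshWithBoundary:
    """Read a volume mesh from the legacy-VTK dialect (see module docs)."""
    points, conn, types, labels, _, _ = _read_vtk(path)
    return _assemble(points, conn, types, labels, path)


def _assemble(points, conn, types, labels, path):
    bad = set(types) - {10, 5}
    if bad:
        names = {14: "pyramid", 13: "wedge", 12: "hexahedron"}
        what = ", ".join(names.get(t, f"type {t}") for t in sorted(bad))
        raise UnsupportedCellError(
            f"unsupported cell type(s) in {path}: {what}; only tetrahedra and "
            "boundary triangles are supported"
        )
    tets, tris, tri_labels = [], [], []
    for i, (cell, t) in enumerate(zip(conn, types)):
        if t == 10:
            if len(cell) != 4:
                raise MeshFormatError(f"tetrahedron cell {i} has {len(cell)} vertices")
            tets.append(cell)
        else:
            if len(cell) != 3:
                raise MeshFormatError(f"triangle cell {i} has {len(cell)} vertices")
            tris.append(cell)
            if labels is None:
                raise MeshFormatError("boundary triangles present but no boundary_label array")
            code = labels[i]
            if code not in CODE_LABELS:
                raise MeshFormatError(f"unknown boundary label code {code} on cell {i}")
            tri_labels.append(CODE_LABELS[code])
    tets = np.array(tets, dtype=np.int64).reshape(-1, 4)
    # repair orientation: readers accept either orientation, the type demands > 0
    v = points[tets]
    vol = np.einsum("ij,ij->i", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0])
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return build_volume_mesh(points, tets, np.array(tris, dtype=np.int64).reshape(-1, 3), tri_labels)


def read_field(path):
    """Read mesh + velocity frames; returns (mesh, VelocityField)."""
    points, conn, types, labels, frames, meta = _read_vtk(path)
    mesh = _assemble(points, conn, types, labels, path)
    if not frames:
        raise MeshFormatError(f"{path} contains no velocity_frame_<k> arrays")
    if "period" not in meta:
        raise MeshFormatError("title line lacks period=<s> metadata")
    period = meta["period"]
    ks = sorted(int(name.rsplit("_", 1)[1]) for name in frames)
    values = np.stack([frames[f"velocity_frame_{k}"] for k in ks])
    n = len(ks)
    times = np.arange(n) * period / n
    return mesh, VelocityField(frame_times=times, values=values, period=period)


# ---------------------------------------------------------------------------
# STL surface + label sidecar

def write_surface_stl(surface: SurfaceMesh, stl_path, labels_path):
    import trimesh

    tm = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    Path(stl_path).write_text(
        tm.export(file_type="stl_ascii")
    )
    with open(labels_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["triangle_index", "label"])
        for i, lab in enumerate(surface.face_labels):
            w.writerow([i, lab])


def read_mesh_with_stl(volume_path, stl_path, labels_path) -> VolumeMeshWithBoundary:
    """Volume VTK + ASCII STL surface + label sidecar.

    Surface vertices are matched to volume vertices by exact coordinate
    match within 1e-9 cm; an unmatched vertex is a topology error.
    """
    import trimesh
    from scipy.spatial import cKDTree

    points, conn, types, labels, _, _ = _read_vtk(volume_path)
    tets = [c for c, t in zip(conn, types) if t == 10]
    bad = set(types) - {10, 5}
    if bad:
        raise UnsupportedCellError(f"unsupported cell types {sorted(bad)} in {volume_path}")
    tets = np.array(tets, dtype=np.int64)
    tm = trimesh.load(str(stl_path), file_type="stl", process=False)
    tree = cKDTree(points)
    dist, idx = tree.query(tm.vertices)
    if np.any(dist > 1e-9):
        raise TopologyError(
            f"{int((dist > 1e-9).sum())} STL vertices have no matching volume vertex"
        )
    tris = idx[np.asarray(tm.faces, dtype=np.int64)]
    with open(labels_path) as fh:
        rows = list(csv.DictReader(fh))
    if len(rows) != len(tris):
        raise TopologyError("label sidecar row count does not match STL triangle count")
    tri_labels = [None] * len(tris)
    for row in rows:
        tri_labels[int(row["triangle_index"])] = row["label"]
    # repair tet orientation as in read_mesh
    v = points[tets]
    vol = np.einsum("ij,ij->i", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0])
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return build_volume_mesh(points, tets, tris, tri_labels)


# ---------------------------------------------------------------------------
# waveform CSV and vitals YAML

def write_waveform(waveform, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "flow_mL_s"])
        for t, q in zip(waveform.times, waveform.flows):
            w.writerow([_FMT % t, _FMT % q])


def read_waveform(path, period: float):
    """Read an inlet waveform CSV; times are shifted to start at 0."""
    import pandas as pd

    from .core import FlowWaveform

    df = pd.read_csv(path)
    for col in ("time_s", "flow_mL_s"):
        if col not in df.columns:
            raise MeshFormatError(f"waveform CSV lacks column {col!r}")
    if len(df) < 4:
        raise SizeError("waveform CSV needs at least 4 rows")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise OrderError("waveform times must be strictly increasing")
    return FlowWaveform(times=times - times[0], flows=df["flow_mL_s"].to_numpy(dtype=float), period=period)


def write_vitals(vitals: SubjectVitals, path):
    data = {
        "systolic_mmHg": float(vitals.systolic),
        "diastolic_mmHg": float(vitals.diastolic),
        "heart_rate_bpm": float(vitals.heart_rate),
        "stroke_volume_mL": float(vitals.stroke_volume),
        "group": vitals.group_label,
        "event": bool(vitals.event_label),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_vitals(path) -> SubjectVitals:
    data = yaml.safe_load(Path(path).read_text())
    return SubjectVitals(
        systolic=data["systolic_mmHg"],
        diastolic=data["diastolic_mmHg"],
        heart_rate=data["heart_rate_bpm"],
        stroke_volume=data["stroke_volume_mL"],
        group_label=data.get("group", "normal"),
        event_label=bool(data.get("event", False)),
    )
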