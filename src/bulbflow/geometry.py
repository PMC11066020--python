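"""Centerline extraction, lumen profiling and the carotid-bulb ROI.

The centerline is computed by marching cross-section centroids: a cutting
plane advances along the running tangent in steps of a quarter local
radius; at each station the plane/mesh cross-section is computed exactly
(plane-tetrahedron polygons), split into connected components, and the
component continuing the current path contributes a centroid and an
equivalent radius sqrt(area/pi).  The first station at which the section
splits into two substantial components marks the bifurcation; the march
then follows the component leading to the ICA outlet.  This is a
deliberately simple alternative to Voronoi/medial-axis centerlines and is
adequate for near-tubular lumens.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import VolumeMeshWithBoundary
from .errors import (
    EmptyRegionError,
    ExtractionError,
    InsufficientExtentError,
    ParameterError,
    TopologyError,
)


@dataclass
class Centerline:
    points: np.ndarray          # (S, 3) cm
    arclength: np.ndarray       # (S,) cm, strictly increasing from 0
    local_radius: np.ndarray    # (S,) cm equivalent radius sqrt(A/pi)
    bifurcation_index: Optional[int] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.local_radius = np.asarray(self.local_radius, dtype=float)
        if np.any(np.diff(self.arclength) <= 0):
            raise ParameterError("arclength must be strictly increasing")
        if np.any(self.local_radius <= 0):
            raise ParameterError("local radii must be positive")


@dataclass
class BulbROI:
    """Bulbar region of interest: lesion (or bifurcation) to 1.5 CCA
    diameters downstream along the trunk-to-ICA path."""

    start_arclength: float
    end_arclength: float
    face_indices: np.ndarray    # indices into the mesh boundary faces
    cell_indices: np.ndarray    # indices into the mesh tetrahedra
    roi_surface_area: float
    roi_volume: float
    cca_diameter: float
    truncated: bool = False

    def to_json_dict(self):
        return {
            "start_arclength_cm": self.start_arclength,
            "end_arclength_cm": self.end_arclength,
            "surface_area_cm2": self.roi_surface_area,
            "volume_cm3": self.roi_volume,
            "cca_diameter_cm": self.cca_diameter,
            "n_faces": int(len(self.face_indices)),
            "n_cells": int(len(self.cell_indices)),
            "truncated": bool(self.truncated),
        }


# ---------------------------------------------------------------------------
# plane cross-sections

def _plane_cross_section(mesh, point, normal, cand):
    """Exact cross-section triangles of candidate tets with a plane.

    Returns per-crossing-cell triangle fans: (cells, tri_pts) where
    ``tri_pts`` is (T, 3, 3) and ``tri_cell`` maps each triangle to its
    cell's position in ``cells``.
    """
    tets = mesh.tetrahedra[cand]
    verts = mesh.vertices[tets]                     # (n, 4, 3)
    dist = (verts - point) @ normal                  # (n, 4)
    dist = np.where(dist == 0.0, 1e-14, dist)
    pos = dist > 0
    npos = pos.sum(axis=1)
    crossing = (npos > 0) & (npos < 4)
    if not np.any(crossing):
        return cand[:0], np.zeros((0, 3, 3)), np.zeros(0, dtype=np.int64)
    tets, verts, dist, pos, npos = (
        tets[crossing], verts[crossing], dist[crossing], pos[crossing], npos[crossing]
    )
    cells = cand[crossing]

    tri_pts, tri_cell = [], []

    def edge_points(v_from, v_to, d_from, d_to):
        t = d_from / (d_from - d_to)
        return v_from + t[..., None] * (v_to - v_from)

    # case: one vertex on its own side (3 intersection points)
    single = (npos == 1) | (npos == 3)
    if np.any(single):
        sv = np.where(npos[single][:, None] == 1, pos[single], ~pos[single])  # lone side
        idx_lone = np.argmax(sv, axis=1)
        rows = np.flatnonzero(single)
        others = np.array([[j for j in range(4) if j != i] for i in idx_lone])
        v_lone = verts[rows, idx_lone]
        d_lone = dist[rows, idx_lone]
        pts = []
        for kk in range(3):
            v_o = verts[rows, others[:, kk]]
            d_o = dist[rows, others[:, kk]]
            pts.append(edge_points(v_lone, v_o, d_lone, d_o))
        tri = np.stack(pts, axis=1)                  # (m, 3, 3)
        tri_pts.append(tri)
        tri_cell.append(rows)

    # case: 2-2 split (4 intersection points forming a planar quad)
    double = npos == 2
    if np.any(double):
        rows = np.flatnonzero(double)
        pm = pos[rows]
        # a, b positive; c, d negative
        ab = np.argsort(~pm, kind="stable", axis=1)[:, :2]
        cd = np.argsort(pm, kind="stable", axis=1)[:, :2]
        va = verts[rows, ab[:, 0]]; vb = verts[rows, ab[:, 1]]
        vc = verts[rows, cd[:, 0]]; vd = verts[rows, cd[:, 1]]
        da = dist[rows, ab[:, 0]]; db = dist[rows, ab[:, 1]]
        dc = dist[rows, cd[:, 0]]; dd = dist[rows, cd[:, 1]]
        pac = edge_points(va, vc, da, dc)
        pad = edge_points(va, vd, da, dd)
        pbd = edge_points(vb, vd, db, dd)
        pbc = edge_points(vb, vc, db, dc)
        # quad (pac, pad, pbd, pbc) is convex in this order; two triangles
        tri_pts.append(np.stack([pac, pad, pbd], axis=1))
        tri_cell.append(rows)
        tri_pts.append(np.stack([pac, pbd, pbc], axis=1))
        tri_cell.append(rows)

    tri_pts = np.concatenate(tri_pts)
    tri_cell = np.concatenate(tri_cell)
    return cells, tri_pts, tri_cell


def _section_components(mesh, cells, tri_pts, tri_cell, merge_tol):
    """Group crossing cells into connected components of the cross-section.

    Cells sharing a mesh vertex are connected; components whose area
    centroids lie within ``merge_tol`` are merged (this heals the
    non-conformal union joints of the synthetic bifurcation).
    Returns a list of dicts (area, centroid, cells).
    """
    n = len(cells)
    tets = mesh.tetrahedra[cells]
    uverts, inv = np.unique(tets, return_inverse=True)
    inv = inv.reshape(n, 4)
    rows = np.repeat(np.arange(n), 4)
    graph = sparse.coo_matrix(
        (np.ones(4 * n), (rows, inv.ravel())), shape=(n, len(uverts))
    )
    big = sparse.bmat(
        [[None, graph], [graph.T, None]], format="csr"
    )
    ncomp, lab = connected_components(big, directed=False)
    cell_lab = lab[:n]

    areas_tri = 0.5 * np.linalg.norm(
        np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0]), axis=1
    )
    cent_tri = tri_pts.mean(axis=1)
    comp_of_tri = cell_lab[tri_cell]

    comps = []
    for c in np.unique(cell_lab):
        sel = comp_of_tri == c
        a = areas_tri[sel].sum()
        if a <= 0:
            continue
        centroid = (areas_tri[sel, None] * cent_tri[sel]).sum(axis=0) / a
        comps.append({"area": a, "centroid": centroid, "cells": cells[cell_lab == c]})

    # merge geometrically coincident components (union-mesh overlap)
    merged = True
    while merged and len(comps) > 1:
        merged = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if np.linalg.norm(comps[i]["centroid"] - comps[j]["centroid"]) < merge_tol:
                    a, b = comps[i], comps[j]
                    tot = a["area"] + b["area"]
                    a["centroid"] = (a["area"] * a["centroid"] + b["area"] * b["centroid"]) / tot
                    a["area"] = tot
                    a["cells"] = np.concatenate([a["cells"], b["cells"]])
                    del comps[j]
                    merged = True
                    break
            if merged:
                break
    return comps


def extract_centerline(mesh: VolumeMeshWithBoundary, source="inlet",
                       target="outlet_ica", step_factor=0.25,
                       max_steps=800) -> Centerline:
    """March cross-section centroids from the inlet to the ICA outlet."""
    surf = mesh.boundary
    inlet_faces = surf.faces_with_label(source)
    if not len(inlet_faces):
        raise TopologyError(f"mesh has no {source!r} faces")
    areas = surf.face_areas[inlet_faces]
    inlet_area = areas.sum()
    inlet_centroid = (areas[:, None] * surf.face_centroids[inlet_faces]).sum(axis=0) / inlet_area
    inlet_normal = (areas[:, None] * surf.face_normals[inlet_faces]).sum(axis=0)
    inlet_normal /= np.linalg.norm(inlet_normal)
    tangent = -inlet_normal                         # inward

    out_faces = surf.faces_with_label(target)
    if not len(out_faces):
        raise TopologyError(f"mesh has no {target!r} faces")
    oa = surf.face_areas[out_faces]
    outlet_centroid = (oa[:, None] * surf.face_centroids[out_faces]).sum(axis=0) / oa.sum()

    centroids = mesh.tet_centroids
    tree = mesh._cache.setdefault("centroid_tree", cKDTree(centroids))
    edges = mesh.vertices[mesh.tetrahedra]
    h_med = np.median(
        np.linalg.norm(edges[:, 1] - edges[:, 0], axis=1)
    )

    r_loc = np.sqrt(inlet_area / np.pi)
    point = inlet_centroid + 0.4 * r_loc * tangent

    pts, arcs, rads = [], [], []
    bif_index = None
    bif_candidate = None
    arc = 0.0
    prev_pt = None

    for step_i in range(max_steps):
        step = step_factor * r_loc
        cand = np.array(
            tree.query_ball_point(point, 3.0 * r_loc + 2.0 * h_med), dtype=np.int64
        )
        comps = []
        if len(cand):
            cells, tri_pts, tri_cell = _plane_cross_section(mesh, point, tangent, cand)
            if len(cells):
                comps = _section_components(
                    mesh, cells, tri_pts, tri_cell, merge_tol=0.25 * r_loc
                )
        if not comps:
            if pts and (
                np.linalg.norm(point - outlet_centroid) < 2.5 * r_loc
            ):
                break
            if not pts:
                raise TopologyError("no lumen cross-section at the inlet; disconnected lumen?")
            raise ExtractionError(
                "cross-section vanished before reaching the outlet",
                last_arclength=arcs[-1],
            )

        if bif_index is None:
            ref = point if prev_pt is None else prev_pt
            follow = min(comps, key=lambda cpt: np.linalg.norm(cpt["centroid"] - ref))
        else:
            follow = min(
                comps, key=lambda cpt: np.linalg.norm(cpt["centroid"] - outlet_centroid)
            )

        # detect the split into two substantial sections (confirmed twice)
        if bif_index is None:
            others = [
                cpt for cpt in comps
                if cpt is not follow and cpt["area"] >= 0.25 * follow["area"]
            ]
            if others:
                if bif_candidate is not None and bif_candidate == len(pts) - 1:
                    # branch point: the last station with a single section
                    bif_index = max(bif_candidate - 1, 0)
                    follow = min(
                        comps,
                        key=lambda cpt: np.linalg.norm(cpt["centroid"] - outlet_centroid),
                    )
                else:
                    bif_candidate = len(pts)
            else:
                bif_candidate = None

        centroid = follow["centroid"]
        # keep the station on the cutting plane through `point`
        centroid = centroid - np.dot(centroid - point, tangent) * tangent
        r_new = np.sqrt(follow["area"] / np.pi)

        if prev_pt is not None:
            ds = np.linalg.norm(centroid - prev_pt)
            if ds < 1e-9:
                raise ExtractionError("centerline stalled", last_arclength=arc)
            arc += ds
            new_dir = (centroid - prev_pt) / ds
            tangent = 0.5 * tangent + 0.5 * new_dir
            tangent /= np.linalg.norm(tangent)
        pts.append(centroid)
        arcs.append(arc)
        rads.append(r_new)
        prev_pt = centroid
        r_loc = r_new
        point = centroid + step * tangent

        if np.linalg.norm(centroid - outlet_centroid) < max(step, 0.75 * r_loc):
            break
    else:
        raise ExtractionError("centerline exceeded the step budget", last_arclength=arc)

    return Centerline(
        points=np.array(pts),
        arclength=np.array(arcs),
        local_radius=np.array(rads),
        bifurcation_index=bif_index,
    )


# ---------------------------------------------------------------------------
# lumen profiling

def percent_narrowing(centerline: Centerline, lesion_index=None, window_factor=2.0):
    """ECST-style narrowing: 100 (1 - d_min / d_ref).

    ``d_ref`` is the expected normal diameter at the lesion, estimated by
    linear interpolation between the median diameters of windows proximal
    and distal to the lesion (window width = ``window_factor`` x local
    radius, separated from the lesion by one window).
    """
    s = centerline.arclength
    d = 2.0 * centerline.local_radius
    if lesion_index is None:
        # search only where both reference windows contain stations
        w_typ = window_factor * float(np.median(centerline.local_radius))
        valid = (s >= s[0] + 1.05 * w_typ) & (s <= s[-1] - 1.05 * w_typ)
        if not valid.any():
            raise InsufficientExtentError(
                "radius profile does not cover three windows around the lesion"
            )
        cand_idx = np.flatnonzero(valid)
        lesion_index = int(cand_idx[np.argmin(d[cand_idx])])
    s0 = s[lesion_index]
    w = window_factor * centerline.local_radius[lesion_index]
    prox = (s >= s0 - 3 * w) & (s <= s0 - w)
    dist = (s >= s0 + w) & (s <= s0 + 3 * w)
    if not prox.any() or not dist.any():
        raise InsufficientExtentError(
            "radius profile does not cover three windows around the lesion"
        )
    sp, dp = s[prox].mean(), np.median(d[prox])
    sd_, dd_ = s[dist].mean(), np.median(d[dist])
    d_ref = dp + (dd_ - dp) * (s0 - sp) / (sd_ - sp)
    return 100.0 * (1.0 - d[lesion_index] / d_ref)


def cca_diameter(centerline: Centerline, inlet_offset=0.5):
    """CCA diameter: 2 x median equivalent radius over the inlet-adjacent
    ``inlet_offset`` cm of arclength (median for robustness)."""
    sel = centerline.arclength <= centerline.arclength[0] + inlet_offset
    return 2.0 * float(np.median(centerline.local_radius[sel]))


def clip_bulb_roi(mesh: VolumeMeshWithBoundary, centerline: Centerline,
                  lesion_arclength, cca_diameter_cm, multiplier=1.5,
                  distance_factor=2.2) -> BulbROI:
    """Clip the bulbar ROI: lesion to ``multiplier`` CCA diameters downstream.

    Membership: a wall face / cell belongs to the ROI when its centroid's
    projected arclength (arclength of the nearest centerline station) lies
    in the span and it sits within ``distance_factor`` local radii of the
    path (which excludes the ECA side of a bifurcation).
    """
    start = float(lesion_arclength)
    end = start + multiplier * float(cca_diameter_cm)
    ctree = cKDTree(centerline.points)

    def project(points):
        dist_, idx = ctree.query(points)
        return centerline.arclength[idx], dist_, centerline.local_radius[idx]

    wall_faces = mesh.boundary.faces_with_label("wall")
    fs, fdist, frad = project(mesh.boundary.face_centroids[wall_faces])
    f_in = (fs >= start) & (fs <= end) & (fdist <= distance_factor * frad)
    cs, cdist, crad = project(mesh.tet_centroids)
    c_in = (cs >= start) & (cs <= end) & (cdist <= distance_factor * crad)
    if not f_in.any() or not c_in.any():
        raise EmptyRegionError("bulb ROI contains no faces or cells")

    truncated = end > centerline.arclength[-1] + 1e-9
    if truncated:
        warnings.warn("bulb ROI extends beyond the meshed domain", stacklevel=2)
    return BulbROI(
        start_arclength=start,
        end_arclength=end,
        face_indices=wall_faces[f_in],
        cell_indices=np.flatnonzero(c_in),
        roi_surface_area=float(mesh.boundary.face_areas[wall_faces[f_in]].sum()),
        roi_volume=float(mesh.tet_volumes[np.flatnonzero(c_in)].sum()),
        cca_diameter=float(cca_diameter_cm),
        truncated=truncated,
    )


def export_roi(roi: BulbROI, json_path, csv_path=None):
    Path = __import__("pathlib").Path
    Path(json_path).write_text(json.dumps(roi.to_json_dict(), indent=1))
    if csv_path is not None:
        import csv as _csv

        with open(csv_path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["kind", "index"])
            for i in roi.face_indices:
                w.writerow(["face", int(i)])
            for i in roi.cell_indices:
                w.writerow(["cell", int(i)])
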