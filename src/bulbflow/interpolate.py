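"""Point location and barycentric interpolation on tetrahedral meshes."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _locator(mesh):
    cache = mesh._cache
    if "kdtree" not in cache:
        cache["kdtree"] = cKDTree(mesh.tet_centroids)
    if "bary_inv" not in cache:
        v = mesh.vertices[mesh.tetrahedra]
        T = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)
        cache["bary_inv"] = np.linalg.inv(T)
    return cache["kdtree"], cache["bary_inv"]


def locate_points(mesh, points, k=48, tol=1e-9):
    """Find the tetrahedron containing each point.

    Returns ``(tet_idx, weights)`` where ``tet_idx`` is -1 for points not
    inside any tested candidate and ``weights`` are the 4 barycentric
    coordinates (zeros for unlocated points).  Candidates are the ``k``
    tets with nearest centroids, which is ample for the probe distances
    used here (a fraction of the local radius).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree, Tinv = _locator(mesh)
    k = min(k, len(mesh.tetrahedra))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    n = len(points)
    tet_idx = np.full(n, -1, dtype=np.int64)
    weights = np.zeros((n, 4))
    unresolved = np.arange(n)
    v0 = mesh.vertices[mesh.tetrahedra[:, 0]]
    for j in range(k):
        if not len(unresolved):
            break
        tj = cand[unresolved, j]
        lam = np.einsum("nij,nj->ni", Tinv[tj], points[unresolved] - v0[tj])
        ok = (lam.min(axis=1) >= -tol) & (lam.sum(axis=1) <= 1 + tol)
        hit = unresolved[ok]
        tet_idx[hit] = tj[ok]
        weights[hit, 1:] = lam[ok]
        weights[hit, 0] = 1.0 - lam[ok].sum(axis=1)
        unresolved = unresolved[~ok]

    if len(unresolved):
        # exact fallback: all tets whose centroid lies within 1.5 cell
        # diameters (k nearest centroids can miss the containing tet on
        # coarse meshes, where cells are large compared to their spacing)
        if "h_max" not in mesh._cache:
            ve = mesh.vertices[mesh.tetrahedra]
            mesh._cache["h_max"] = float(
                max(
                    np.linalg.norm(ve[:, a] - ve[:, b], axis=1).max()
                    for a in range(4) for b in range(a + 1, 4)
                )
            )
        radius = 1.5 * mesh._cache["h_max"]
        for i in unresolved:
            cand_i = np.asarray(tree.query_ball_point(points[i], radius), dtype=np.int64)
            if not len(cand_i):
                continue
            lam = np.einsum("nij,nj->ni", Tinv[cand_i], points[i] - v0[cand_i])
            ok = (lam.min(axis=1) >= -tol) & (lam.sum(axis=1) <= 1 + tol)
            if ok.any():
                j = int(np.argmax(ok))
                tet_idx[i] = cand_i[j]
                weights[i, 1:] = lam[j]
                weights[i, 0] = 1.0 - lam[j].sum()
    return tet_idx, weights


def interpolate_velocity(mesh, field, points, k=48):
    """Barycentric interpolation of the velocity field at arbitrary points.

    Returns ``(values, inside)`` with ``values`` of shape (F, n, 3); rows
    for points outside the mesh are zero and flagged False in ``inside``.
    """
    tet_idx, w = locate_points(mesh, points, k=k)
    inside = tet_idx >= 0
    safe = np.where(inside, tet_idx, 0)
    verts = mesh.tetrahedra[safe]          # (n, 4)
    vals = np.einsum("fnkc,nk->fnc", field.values[:, verts, :], w)
    vals[:, ~inside, :] = 0.0
    return vals, inside
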