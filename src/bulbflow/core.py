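"""Shared domain types for the carotid-bulb hemodynamics pipeline.

All containers are thin, validated wrappers around numpy arrays in CGS
units (see :mod:`bulbflow.units`).  They are deliberately dumb: operations
live in the geometry / wall / volumetric / stats modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError, SizeError, TopologyError

GROUP_LABELS = ("caw", "atherosclerosis", "normal")
SURFACE_LABELS = ("wall", "inlet", "outlet_ica", "outlet_eca")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model: dynamic viscosity (Poise), density (g/cm^3)."""

    viscosity: float = 0.04
    density: float = 1.06

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ParameterError("viscosity and density must be positive")


BLOOD = FluidProperties()


@dataclass
class FlowWaveform:
    """Periodic inlet volumetric flow Q(t).

    times are in seconds (strictly increasing, first sample at 0, last
    sample at or before ``period``); flows in mL/s.  The waveform is
    treated as periodic with period ``period``.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.flows.shape:
            raise ParameterError("times and flows must be matching 1D arrays")
        if len(self.times) < 4:
            raise SizeError("waveform needs at least 4 samples")
        if abs(self.times[0]) > 1e-12:
            raise ParameterError("waveform times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("waveform times must be strictly increasing")
        if self.period <= 0 or self.times[-1] > self.period + 1e-12:
            raise ParameterError("last sample must lie within one period")

    def _closed(self):
        """Samples extended to t = period by periodic wrap-around."""
        if self.period - self.times[-1] > 1e-12:
            t = np.append(self.times, self.period)
            q = np.append(self.flows, self.flows[0])
        else:
            t, q = self.times, self.flows
        return t, q

    @property
    def mean_flow(self) -> float:
        """Time average of Q over one period (trapezoid, periodic)."""
        t, q = self._closed()
        return float(np.trapezoid(q, t) / self.period)

    @property
    def peak_flow(self) -> float:
        return float(self.flows.max())

    def __call__(self, t):
        """Periodic linear interpolation of Q at time(s) t."""
        tc, qc = self._closed()
        return np.interp(np.mod(t, self.period), tc, qc)


@dataclass
class SubjectVitals:
    """Clinical measurements used for boundary-condition estimation."""

    systolic: float
    diastolic: float
    heart_rate: float
    stroke_volume: float
    group_label: str = "normal"
    event_label: bool = False

    def __post_init__(self):
        if not (self.systolic > self.diastolic > 0):
            raise ParameterError("need systolic > diastolic > 0")
        if self.heart_rate <= 0 or self.stroke_volume <= 0:
            raise ParameterError("heart rate and stroke volume must be positive")
        if self.group_label not in GROUP_LABELS:
            raise ParameterError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )

    @property
    def pulse_pressure(self) -> float:
        """Pulse pressure SBP - DBP in mmHg (always derived, never stored)."""
        return self.systolic - self.diastolic


@dataclass
class SurfaceMesh:
    """Triangulated lumen boundary with per-face labels and outward normals."""

    vertices: np.ndarray          # (V, 3) cm
    triangles: np.ndarray         # (M, 3) int
    face_labels: np.ndarray       # (M,) str, subset of SURFACE_LABELS
    face_normals: np.ndarray      # (M, 3) unit, outward from the lumen

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.face_labels = np.asarray(self.face_labels, dtype=object)
        self.face_normals = np.asarray(self.face_normals, dtype=float).reshape(-1, 3)
        nv = len(self.vertices)
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= nv):
            raise TopologyError("triangle references an invalid vertex")
        if len(self.face_labels) != len(self.triangles) or len(self.face_normals) != len(self.triangles):
            raise TopologyError("labels/normals must match triangle count")
        bad = set(self.face_labels) - set(SURFACE_LABELS)
        if bad:
            raise TopologyError(f"unknown face labels: {sorted(bad)}")
        norms = np.linalg.norm(self.face_normals, axis=1)
        if self.face_normals.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise TopologyError("face normals must be unit length within 1e-6")

    @property
    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def faces_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.face_labels == label)


@dataclass
class VolumeMeshWithBoundary:
    """Tetrahedral lumen mesh plus its labeled boundary surface.

    ``boundary_vertex_map`` maps each boundary-surface vertex to its index
    in the volume vertex array (injective by construction).  ``axis_info``
    optionally carries the analytic axis metadata of generated meshes
    (per-vertex branch id, axial coordinate, radial distance, local radius
    and axis direction) used by the synthetic field sampler.
    """

    vertices: np.ndarray          # (P, 3) cm
    tetrahedra: np.ndarray        # (K, 4) int, positively oriented
    boundary: SurfaceMesh
    boundary_vertex_map: np.ndarray  # (B,) int into vertices
    axis_info: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=np.int64).reshape(-1, 4)
        self.boundary_vertex_map = np.asarray(self.boundary_vertex_map, dtype=np.int64)
        if self.tetrahedra.min(initial=0) < 0 or self.tetrahedra.max(initial=-1) >= len(self.vertices):
            raise TopologyError("tetrahedron references an invalid vertex")
        vols = self.signed_tet_volumes
        if np.any(vols <= 0):
            raise TopologyError(
                f"{int((vols <= 0).sum())} tetrahedra are not positively oriented"
            )
        if len(np.unique(self.boundary_vertex_map)) != len(self.boundary_vertex_map):
            raise TopologyError("boundary vertex map is not injective")
        if len(self.boundary_vertex_map) != len(self.boundary.vertices):
            raise TopologyError("boundary vertex map length mismatch")
        d = np.abs(self.vertices[self.boundary_vertex_map] - self.boundary.vertices)
        if d.size and d.max() > 1e-9:
            raise TopologyError("boundary vertices do not coincide with volume vertices")
        self._cache = {}

    @property
    def signed_tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tetrahedra]
        return np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        ) / 6.0

    @property
    def tet_volumes(self) -> np.ndarray:
        if "tet_volumes" not in self._cache:
            self._cache["tet_volumes"] = np.abs(self.signed_tet_volumes)
        return self._cache["tet_volumes"]

    @property
    def tet_centroids(self) -> np.ndarray:
        if "tet_centroids" not in self._cache:
            self._cache["tet_centroids"] = self.vertices[self.tetrahedra].mean(axis=1)
        return self._cache["tet_centroids"]

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes.sum())

    @property
    def boundary_triangles_volume_idx(self) -> np.ndarray:
        """Boundary triangles expressed in volume vertex indices."""
        return self.boundary_vertex_map[self.boundary.triangles]


@dataclass
class VelocityField:
    """Frames x volume-vertices 3-vector field (cm/s) over one cardiac cycle."""

    frame_times: np.ndarray   # (F,) s, uniform, first = 0
    values: np.ndarray        # (F, P, 3) cm/s
    period: float

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frame_times) < 8:
            raise SizeError("velocity field needs at least 8 frames")
        if abs(self.frame_times[0]) > 1e-12:
            raise ParameterError("frame times must start at 0")
        dt = np.diff(self.frame_times)
        if np.any(np.abs(dt - dt[0]) > 1e-9):
            raise ParameterError("frame spacing must be uniform within 1e-9")
        if self.values.ndim != 3 or self.values.shape[0] != len(self.frame_times) or self.values.shape[2] != 3:
            raise ParameterError("values must have shape (n_frames, n_vertices, 3)")
        if self.period <= 0 or self.frame_times[-1] >= self.period:
            raise ParameterError("frames must cover exactly one period (last < period)")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def speeds(self) -> np.ndarray:
        """Per-frame per-vertex speed magnitudes, shape (F, P)."""
        return np.linalg.norm(self.values, axis=2)
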