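"""Low-velocity volume fractions and flow stasis inside the bulb ROI.

A tetrahedron counts as "low velocity" at a frame when its centroid speed
(the mean of its four vertex speed magnitudes) is strictly below the
threshold; the low-velocity volume percentage is the volume of those cells
over the ROI volume.  Stasis is the percentage of cardiac-cycle frames in
which a low-velocity region is present, where "present" means the
low-velocity volume exceeds a small presence floor (default 0.1% of the
ROI volume; a literal > 0 rule is available via ``presence_floor=0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import VelocityField, VolumeMeshWithBoundary
from .errors import EmptyRegionError, ParameterError


@dataclass
class VolumeFractionCurve:
    """Low-velocity volume percentage per cardiac frame."""

    frame_times: np.ndarray
    values: np.ndarray          # (F,) percent of ROI volume
    threshold: float            # cm/s

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 100)):
            raise ParameterError("volume fractions must lie in [0, 100]")

    @property
    def time_average(self) -> float:
        """Uniform frames: the time average is the arithmetic mean."""
        return float(self.values.mean())


@dataclass
class MetricSummary:
    """Per-subject scalar biomarkers (the unit of cohort statistics)."""

    subject_id: str
    group_label: str
    event_label: bool
    low_shear_area_pct: Optional[float] = None
    high_osi_area_pct: Optional[float] = None
    low_velocity_volume_pct: Optional[float] = None
    stasis_pct: Optional[float] = None

    def __post_init__(self):
        for name in ("low_shear_area_pct", "high_osi_area_pct",
                     "low_velocity_volume_pct", "stasis_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ParameterError(f"{name} must be in [0, 100], got {v}")


def _cell_speeds(field: VelocityField, mesh: VolumeMeshWithBoundary, cells):
    """(F, n_cells) centroid speeds: mean of the 4 vertex speed magnitudes."""
    speeds = field.speeds()                  # (F, P)
    return speeds[:, mesh.tetrahedra[cells]].mean(axis=2)


def low_velocity_volume_pct(field, mesh, roi, threshold, frame):
    """Percent of ROI volume with centroid speed strictly below threshold."""
    if not len(roi.cell_indices):
        raise EmptyRegionError("ROI contains no cells")
    cells = roi.cell_indices
    vols = mesh.tet_volumes[cells]
    sp = _cell_speeds(field, mesh, cells)[frame]
    return 100.0 * vols[sp < threshold].sum() / vols.sum()


def volume_fraction_curve(field, mesh, roi, threshold) -> VolumeFractionCurve:
    """Low-velocity volume percentage evaluated at every frame."""
    if not len(roi.cell_indices):
        raise EmptyRegionError("ROI contains no cells")
    cells = roi.cell_indices
    vols = mesh.tet_volumes[cells]
    sp = _cell_speeds(field, mesh, cells)    # (F, n)
    vals = 100.0 * (vols[None, :] * (sp < threshold)).sum(axis=1) / vols.sum()
    return VolumeFractionCurve(
        frame_times=field.frame_times.copy(), values=vals, threshold=threshold
    )


def stasis_pct(curve: VolumeFractionCurve, presence_floor=0.1):
    """Percent of frames in which a low-velocity region is present."""
    if not len(curve.values):
        raise EmptyRegionError("empty volume-fraction curve")
    if presence_floor < 0:
        raise ParameterError("presence_floor must be >= 0")
    return 100.0 * float((curve.values > presence_floor).sum()) / len(curve.values)
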