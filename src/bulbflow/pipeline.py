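"""End-to-end orchestration: cohort -> per-subject ROI and biomarkers ->
threshold sweep -> group comparison report.

Per-subject failures are isolated: the failing subject is recorded in the
manifest and the cohort statistics are computed on the survivors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dfield, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .core import FluidProperties
from . import geometry, stats, synthetic, volumetric, wall

log = logging.getLogger("bulbflow")

VELOCITY_CANDIDATES = (0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0)


@dataclass(frozen=True)
class PipelineConfig:
    viscosity: float = 0.04                  # Poise
    density: float = 1.06                    # g/cm^3
    low_shear_threshold: float = 10.0        # s^-1
    velocity_candidates: tuple = VELOCITY_CANDIDATES   # cm/s
    osi_top_pct: float = 1.0                 # pooled upper-percentile for high OSI
    roi_multiplier: float = 1.5              # CCA diameters downstream
    frames_per_cycle: int = 20
    presence_floor_pct: float = 0.1          # % of ROI volume
    probe_fraction: float = 0.1              # of local radius, WSS probe depth
    narrowing_detect_pct: float = 5.0        # below this, use bifurcation/anchor
    seed: int = 0

    def __post_init__(self):
        if min(self.low_shear_threshold, self.roi_multiplier, self.osi_top_pct) <= 0:
            raise ValueError("thresholds and the ROI multiplier must be positive")
        if any(c <= 0 for c in self.velocity_candidates):
            raise ValueError("velocity candidates must be positive")

    @property
    def fluid(self) -> FluidProperties:
        return FluidProperties(viscosity=self.viscosity, density=self.density)

    def to_dict(self):
        d = asdict(self)
        d["velocity_candidates"] = list(self.velocity_candidates)
        return d

    @classmethod
    def from_yaml(cls, path):
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "velocity_candidates" in data:
            data["velocity_candidates"] = tuple(data["velocity_candidates"])
        return cls(**data)


@dataclass
class SubjectResult:
    summary: volumetric.MetricSummary
    curves: dict                     # candidate threshold -> VolumeFractionCurve
    osi_field: Optional[wall.WallScalarField]
    shear_field: Optional[wall.WallScalarField]
    roi: geometry.BulbROI
    narrowing_pct: float


def _locate_lesion(subject, centerline, config):
    """Lesion arclength on the trunk->ICA path.

    Narrowed lumens use the narrowest station; otherwise the bifurcation
    station, or (for tube geometries) the stored anchor point.
    """
    try:
        narrowing = geometry.percent_narrowing(centerline)
    except Exception:
        narrowing = 0.0
    d = 2.0 * centerline.local_radius
    if narrowing >= config.narrowing_detect_pct:
        interior = slice(2, max(3, len(d) - 2))
        idx = 2 + int(np.argmin(d[interior]))
        return centerline.arclength[idx], narrowing
    if centerline.bifurcation_index is not None:
        return centerline.arclength[centerline.bifurcation_index], narrowing
    anchor = subject.info.get("lesion_anchor")
    if anchor is None:
        raise geometry.ExtractionError(
            "no narrowing, no bifurcation and no lesion anchor for ROI placement"
        )
    idx = int(np.argmin(np.linalg.norm(centerline.points - np.asarray(anchor), axis=1)))
    return centerline.arclength[idx], narrowing


def analyze_subject(subject, config: PipelineConfig,
                    compute_wall_metrics=True) -> SubjectResult:
    """Run the per-subject pipeline: centerline, ROI, wall and volume metrics.

    The returned summary's threshold-dependent entries (low-velocity
    volume, stasis) are evaluated at 3 cm/s by default and re-evaluated by
    the cohort driver once the sweep has chosen the operating threshold;
    the high-OSI area needs the pooled threshold and is filled in by the
    driver as well.
    """
    cl = geometry.extract_centerline(subject.mesh)
    d_cca = geometry.cca_diameter(cl)
    lesion_s, narrowing = _locate_lesion(subject, cl, config)
    roi = geometry.clip_bulb_roi(
        subject.mesh, cl, lesion_s, d_cca, multiplier=config.roi_multiplier
    )
    curves = {
        cand: volumetric.volume_fraction_curve(subject.field, subject.mesh, roi, cand)
        for cand in config.velocity_candidates
    }
    osi_field = shear_field = None
    low_shear = None
    if compute_wall_metrics:
        radius = wall.wall_local_radius_from_centerline(subject.mesh, cl)
        wss = wall.compute_wss(
            subject.field, subject.mesh, config.fluid,
            probe_fraction=config.probe_fraction, local_radius=radius,
        )
        osi_field = wall.osi(wss)
        shear_field = wall.shear_rate(wss, config.fluid)
        low_shear = wall.low_shear_area_pct(shear_field, roi, config.low_shear_threshold)
    default_thr = 3.0 if 3.0 in curves else sorted(curves)[0]
    summary = volumetric.MetricSummary(
        subject_id=subject.subject_id,
        group_label=subject.group,
        event_label=subject.vitals.event_label,
        low_shear_area_pct=low_shear,
        high_osi_area_pct=None,
        low_velocity_volume_pct=curves[default_thr].time_average,
        stasis_pct=volumetric.stasis_pct(curves[default_thr], config.presence_floor_pct),
    )
    return SubjectResult(
        summary=summary, curves=curves, osi_field=osi_field,
        shear_field=shear_field, roi=roi, narrowing_pct=narrowing,
    )


def run_cohort_analysis(subjects, config: PipelineConfig,
                        compute_wall_metrics=True):
    """Analyze every subject, pool thresholds, sweep and summarize.

    Returns a dict with per-subject summaries, the ROC sweep, the pooled
    OSI threshold, group comparisons and a failure list.
    """
    results, failures = {}, []
    for s in subjects:
        t0 = time.perf_counter()
        try:
            results[s.subject_id] = analyze_subject(
                s, config, compute_wall_metrics=compute_wall_metrics
            )
            status = "ok"
        except Exception as e:   # noqa: BLE001 - per-subject isolation
            failures.append((s.subject_id, f"{type(e).__name__}: {e}"))
            status = f"failed: {type(e).__name__}"
        log.info("stage=analyze subject=%s elapsed=%.2fs status=%s",
                 s.subject_id, time.perf_counter() - t0, status)
    if not results:
        raise RuntimeError("all subjects failed")

    osi_threshold = None
    if compute_wall_metrics:
        osi_threshold = stats.pooled_percentile_threshold(
            [r.osi_field for r in results.values()], "upper", config.osi_top_pct
        )
        for r in results.values():
            r.summary.high_osi_area_pct = wall.high_osi_area_pct(
                r.osi_field, r.roi, osi_threshold
            )

    labels = np.array([r.summary.event_label for r in results.values()])
    scores_by_cand = {
        cand: np.array([r.curves[cand].time_average for r in results.values()])
        for cand in config.velocity_candidates
    }
    best_threshold, roc_results = stats.threshold_sweep(scores_by_cand, labels)

    for r in results.values():
        curve = r.curves[best_threshold]
        r.summary.low_velocity_volume_pct = curve.time_average
        r.summary.stasis_pct = volumetric.stasis_pct(curve, config.presence_floor_pct)

    summaries = [r.summary for r in results.values()]
    comparisons, stasis_full = stats.group_summary_table(summaries)
    return {
        "results": results,
        "summaries": summaries,
        "failures": failures,
        "osi_threshold": osi_threshold,
        "best_threshold": best_threshold,
        "roc": roc_results,
        "comparisons": comparisons,
        "stasis_full_counts": stasis_full,
    }


def run_pipeline(config: PipelineConfig, cohort_spec=None, input_dir=None,
                 out_dir=None, compute_wall_metrics=True):
    """Full pipeline: synthesize or load a cohort, analyze, write reports.

    Deterministic given (config, cohort spec seed, inputs); all report
    files use fixed float formatting.
    """
    import pandas as pd

    if (cohort_spec is None) == (input_dir is None):
        raise ValueError("provide exactly one of cohort_spec or input_dir")
    load_failures = []
    if cohort_spec is not None:
        subjects = synthetic.make_cohort(cohort_spec)
    else:
        subjects, load_failures = synthetic.read_cohort(input_dir)

    analysis = run_cohort_analysis(subjects, config,
                                   compute_wall_metrics=compute_wall_metrics)
    analysis["failures"] = load_failures + analysis["failures"]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in analysis["summaries"]:
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group_label,
                "event": int(s.event_label),
                "low_shear_area_pct": s.low_shear_area_pct,
                "high_osi_area_pct": s.high_osi_area_pct,
                "low_velocity_volume_pct": s.low_velocity_volume_pct,
                "stasis_pct": s.stasis_pct,
            })
            (out / f"{s.subject_id}_metrics.json").write_text(
                json.dumps(rows[-1], indent=1, sort_keys=True)
            )
        df = pd.DataFrame(rows).sort_values("subject_id")
        df.to_csv(out / "subjects.csv", index=False, float_format="%.10g")
        roc_payload = {
            "best_threshold_cm_s": analysis["best_threshold"],
            "candidates": {
                str(c): {"auc": r.auc, "gini": r.gini}
                for c, r in analysis["roc"].items()
            },
        }
        (out / "roc.json").write_text(json.dumps(roc_payload, indent=1, sort_keys=True))
        stats.comparisons_to_frame(
            analysis["comparisons"], analysis["stasis_full_counts"]
        ).to_csv(out / "table_groups.csv", index=False, float_format="%.10g")
        config_json = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "seed": getattr(cohort_spec, "seed", None),
            "n_subjects": len(analysis["summaries"]),
            "n_failures": len(analysis["failures"]),
            "failures": [list(f) for f in analysis["failures"]],
            "osi_threshold": analysis["osi_threshold"],
            "best_threshold_cm_s": analysis["best_threshold"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return analysis


def directionality_study(n_seeds=50, base_seed=0, cohort_spec=None,
                         config=None, alpha=0.05):
    """Repeat the cohort experiment across seeds and check the clinical
    contrast: web-group mean stasis and low-velocity volume exceed both
    other groups with significant web-vs-other pairwise comparisons.

    Wall metrics are skipped here: the contrast under test is volumetric.
    Returns (success_fraction, per-seed records).
    """
    config = config or PipelineConfig()
    records = []
    for i in range(n_seeds):
        spec = replace(
            cohort_spec or synthetic.CohortSpec(), seed=int(base_seed) + i
        )
        analysis = run_pipeline(config, cohort_spec=spec,
                                compute_wall_metrics=False)
        comp_st = analysis["comparisons"]["stasis_pct"]
        comp_lv = analysis["comparisons"]["low_velocity_volume_pct"]
        ok = True
        for comp in (comp_st, comp_lv):
            means = dict(zip(comp.group_labels, comp.group_mean))
            if not (means["caw"] > means["atherosclerosis"]
                    and means["caw"] > means["normal"]):
                ok = False
            for other in ("atherosclerosis", "normal"):
                p = comp.pairwise_p.get(("caw", other),
                                        comp.pairwise_p.get((other, "caw")))
                if p is None or p >= alpha:
                    ok = False
        records.append({
            "seed": spec.seed,
            "success": ok,
            "best_threshold": analysis["best_threshold"],
            "stasis_means": dict(zip(comp_st.group_labels, comp_st.group_mean)),
            "low_velocity_means": dict(zip(comp_lv.group_labels, comp_lv.group_mean)),
            "stasis_full_counts": analysis["stasis_full_counts"],
        })
    frac = sum(r["success"] for r in records) / max(len(records), 1)
    return frac, records
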