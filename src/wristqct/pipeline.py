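"""Per-subject orchestration and cohort aggregation.

``run_subject`` executes the full automatic chain on one volume —
calibrate -> align -> VOI -> segment -> morphometry -> micro-FE — with no
interactive steps once the reference slice is known; ``run_cohort`` maps it
over a cohort, joins the per-subject rows with a reference (DXA-like) table
and produces the statistical report.  Failures of individual subjects are
recorded and excluded without aborting the cohort.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, cohort_stats, geometry, microfe, morphometry
from . import segmentation
from .phantom_synth import GroundTruth
from .volume import Volume


@dataclass
class SubjectConfig:
    """Everything needed to process one subject reproducibly."""

    subject_id: str = "S000"
    volume_path: str | None = None          # NIfTI grey volume (or in-memory)
    roi_path: str | None = None             # JSON {material: [[x,y,z], ...]}
    reference_slice: int | None = None
    voi_offset_mm: float = 9.5
    voi_length_mm: float = 10.0
    align: bool = True
    transitional_width: int = 2
    arg_delta: float = 0.01
    porosity_threshold_gcm3: float = 0.600
    run_fe: bool = True
    fe_displacement_mm: float = 0.1
    fe_youngs_modulus: float = 15000.0
    fe_poisson_ratio: float = 0.3
    fe_tol: float = 1e-8
    output_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    calibration_curve: calibration.CalibrationCurve
    morphometry: morphometry.MorphoResult
    fe_summary: dict | None
    stage_timings_s: dict
    warnings: list[str]
    config_hash: str

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, **self.morphometry.to_row()}
        if self.fe_summary:
            row.update({"Stiffness": self.fe_summary["stiffness_N_per_mm"],
                        "Fmax": self.fe_summary["fmax_N"],
                        "Strength": self.fe_summary["strength_N_per_mm2"]})
        return row

    def save_json(self, path: str | Path) -> None:
        payload = {"subject_id": self.subject_id,
                   "config_hash": self.config_hash,
                   "calibration": {
                       "slope": self.calibration_curve.slope_hu_per_grey,
                       "intercept": self.calibration_curve.intercept_hu,
                       "residuals": self.calibration_curve.fit_residuals},
                   "morphometry": self.morphometry.to_row(),
                   "fe": self.fe_summary,
                   "warnings": self.warnings}
        Path(path).write_text(json.dumps(payload, indent=2))


def _load_inputs(config: SubjectConfig, volume, ground_truth):
    if volume is None:
        if config.volume_path is None:
            raise FileNotFoundError("no volume provided and volume_path is unset")
        if not Path(config.volume_path).exists():
            raise FileNotFoundError(f"volume path {config.volume_path!r} "
                                    "does not exist")
        volume = Volume.load(config.volume_path, kind="grey")
    rois = None
    if ground_truth is not None:
        rois = ground_truth.insert_rois
    elif config.roi_path is not None:
        raw = json.loads(Path(config.roi_path).read_text())
        rois = {k: np.asarray(v, int) for k, v in raw.items()}
    if rois is None:
        raise ValueError("phantom ROIs are required (roi_path or ground truth)")
    return volume, rois


def run_subject(config: SubjectConfig, volume: Volume | None = None,
                ground_truth: GroundTruth | None = None) -> SubjectResult:
    """Run the full automatic chain for one subject.

    Synthetic subjects pass ``volume`` and ``ground_truth`` directly (the
    ground truth supplies phantom ROIs and the reference slice, standing in
    for the manual steps a real scan needs); file-based subjects use the
    config paths.  Any stage error propagates with the stage name attached.
    """
    timings: dict[str, float] = {}
    caught: list[str] = []
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        volume, rois = _load_inputs(config, volume, ground_truth)
        timings[stage] = time.perf_counter() - t0

        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")

            stage = "calibration"
            t0 = time.perf_counter()
            means = {m: calibration.extract_roi_stats(volume, r)[0]
                     for m, r in rois.items()}
            curve = calibration.fit_calibration(means)
            hu = calibration.grey_to_hu(volume, curve)
            relation = calibration.build_density_relation()
            timings[stage] = time.perf_counter() - t0

            stage = "alignment"
            t0 = time.perf_counter()
            if config.align:
                coarse = hu.data > 600.0
                hu, _rot = geometry.align_to_long_axis(hu, coarse)
            timings[stage] = time.perf_counter() - t0

            stage = "voi"
            t0 = time.perf_counter()
            ref = config.reference_slice
            if ref is None and ground_truth is not None:
                ref = ground_truth.reference_slice_index
            spec = geometry.VOISpec(config.voi_offset_mm, config.voi_length_mm,
                                    reference_slice=ref)
            hu_voi = geometry.extract_voi(hu, spec)
            timings[stage] = time.perf_counter() - t0

            stage = "segmentation"
            t0 = time.perf_counter()
            bone = segmentation.levelset_bone_mask(hu_voi)
            compartments = segmentation.delineate_compartments(
                bone, hu_voi, transitional_width=config.transitional_width)
            dens_voi = calibration.hu_to_density(hu_voi, relation)
            trab_region = (compartments.data
                           == segmentation.LABEL_TRABECULAR)
            arg = None
            if trab_region.any() and np.ptp(hu_voi.data[trab_region]) > 0:
                arg = segmentation.arg_segment(
                    hu_voi, trab_region, delta_fraction=config.arg_delta)
            pores = segmentation.cortical_porosity_mask(
                dens_voi, compartments.data == segmentation.LABEL_CORTICAL,
                config.porosity_threshold_gcm3)
            timings[stage] = time.perf_counter() - t0

            stage = "morphometry"
            t0 = time.perf_counter()
            morpho = morphometry.compute_morphometry(
                dens_voi, compartments, bone.data > 0,
                trabecular_bone=arg.best_mask & trab_region if arg else None)
            timings[stage] = time.perf_counter() - t0

            stage = "microfe"
            t0 = time.perf_counter()
            fe_summary = None
            if config.run_fe:
                solid = (bone.data > 0) & ~pores
                model = microfe.build_fe_model(
                    solid, hu_voi.voxel_size_mm,
                    E=config.fe_youngs_modulus, nu=config.fe_poisson_ratio)
                fe = microfe.solve_compression(
                    model, config.fe_displacement_mm, tol=config.fe_tol)
                microfe.pistoia_max_force(fe)
                fe.strength_N_per_mm2 = microfe.strength(
                    fe.fmax_N, morpho.mean_area_mm2)
                fe_summary = fe.summary()
            timings[stage] = time.perf_counter() - t0
            caught = [str(w.message) for w in wlist]
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed for subject "
                           f"{config.subject_id}: {err}") from err

    result = SubjectResult(
        subject_id=config.subject_id, calibration_curve=curve,
        morphometry=morpho, fe_summary=fe_summary,
        stage_timings_s=timings, warnings=caught,
        config_hash=config.config_hash())
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.save_json(out / f"{config.subject_id}.json")
    return result


def run_cohort(subject_inputs, reference_table: pd.DataFrame | None = None,
               comparison_plan=None,
               ) -> tuple[pd.DataFrame, cohort_stats.StatsReport, list[dict]]:
    """Process a cohort and build the statistical report.

    ``subject_inputs`` is a list of ``(config, volume, ground_truth)`` tuples
    (volume/ground_truth may be None for file-based configs).  Returns the
    assembled cohort table, the stats report and the exclusion log.
    """
    if len(subject_inputs) < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    rows, excluded = [], []
    for config, vol, gt in subject_inputs:
        try:
            rows.append(run_subject(config, vol, gt).to_row())
        except Exception as err:
            excluded.append({"subject_id": config.subject_id,
                             "error": str(err)})
    table = pd.DataFrame(rows)
    if reference_table is not None:
        table = table.merge(reference_table, on="subject_id", how="left")
    report = cohort_stats.build_report(table, comparison_plan=comparison_plan)
    return table, report, excluded
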