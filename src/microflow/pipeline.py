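"""End-to-end orchestration: register -> segment -> thin -> RPCA -> measure.

Runs the stages in their processing order, records per-stage parameters
and warnings in a JSON-serializable report, and writes per-vessel
velocity and diameter records as CSV. Centerlines are either traced
from the segmented mask or supplied externally as JSON (the practical
equivalent of manually selecting relatively straight vessels).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .diameter import vessel_diameter
from .geometry import CenterlinePath
from .io import ImageSequence, RunConfig, write_results
from .kymo import estimate_velocity
from .register import register_sequence
from .rpca import rpca_decompose, sparse_video, video_to_matrix
from .segment import enhance_vessels, extract_centerlines, segment_vessels, skeletonize

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """Provenance record of one pipeline run."""

    config: dict
    version: str = __version__
    stages: list = field(default_factory=list)
    vessels: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **params) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3),
                            "params": params})

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=_jsonable)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: RunConfig, seq: ImageSequence,
                 out_dir=None, centerlines: list | None = None) -> PipelineReport:
    """Execute the full measurement pipeline on a calibrated sequence.

    Parameters
    ----------
    config
        Validated run parameters.
    seq
        The input video (already calibrated).
    out_dir
        If given, intermediate artifacts and the result CSV are written
        beneath it.
    centerlines
        Optional externally selected CenterlinePath list; when None,
        centerlines are traced from the segmented mask.

    Deterministic: no stage consumes wall-clock state or unseeded
    randomness.
    """
    report = PipelineReport(config=config.to_dict())
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    t = time.perf_counter()
    corrected = register_sequence(seq, template_box=config.template_box,
                                  search_radius_px=config.search_radius_px)
    report.add_stage("register", time.perf_counter() - t,
                     search_radius_px=config.search_radius_px,
                     max_shift=int(np.abs(corrected.shifts).max()))
    if corrected.clipped.any():
        report.warnings.append(
            f"{int(corrected.clipped.sum())} frame(s) hit the search radius")

    # measurement frame: median over the window, robust to passing RBCs
    green = corrected.green()
    median_frame = np.median(green, axis=0)

    t = time.perf_counter()
    enh = enhance_vessels(median_frame, scales_px=config.vesselness_scales_px)
    mask = segment_vessels(enh, threshold=config.segment_threshold,
                           min_object_px=config.min_object_px)
    skel = skeletonize(mask)
    report.add_stage("segment", time.perf_counter() - t,
                     threshold=config.segment_threshold,
                     scales_px=list(config.vesselness_scales_px),
                     mask_px=int(mask.sum()), skeleton_px=int(skel.sum()))

    if centerlines is None:
        centerlines = extract_centerlines(skel, min_length_px=20.0)
    if not centerlines:
        raise RuntimeError("stage 'segment': no usable centerline found")

    t = time.perf_counter()
    window = min(config.rpca_window, seq.n_frames)
    mat = video_to_matrix(corrected)
    mat.D = mat.D[:, :window]
    result = rpca_decompose(mat, lam=config.rpca_lambda, tol=config.rpca_tol,
                            max_iter=config.rpca_max_iter)
    sparse = sparse_video(result, allow_partial=True)
    report.add_stage("rpca", time.perf_counter() - t, window=window,
                     lam=result.lam, iterations=result.iterations,
                     converged=result.converged, residual=result.residual)
    if not result.converged:
        report.warnings.append("RPCA stopped at max_iter before tolerance")

    records = []
    t = time.perf_counter()
    for vid, path in enumerate(centerlines):
        entry = {"vessel_id": vid, "centerline_px": path.length}
        try:
            dia = vessel_diameter(median_frame, path,
                                  interval_px=config.normal_interval_px,
                                  half_length_px=config.profile_half_length_px,
                                  pixel_size_um=config.pixel_size_um)
            entry["diameter_um"] = dia.fwhm_um
            entry["vessel_class"] = dia.vessel_class
            records.append({"timepoint": 0, "vessel_id": vid,
                            "quantity": "diameter", "value": round(dia.fwhm_um, 3),
                            "units": "um"})
        except ValueError as e:
            entry["diameter_error"] = str(e)
            report.warnings.append(f"vessel {vid}: diameter failed ({e})")
        in_band = (config.min_diameter_um <= entry.get("diameter_um", -1.0)
                   <= config.max_diameter_um)
        entry["velocity_selected"] = bool(in_band)
        if in_band:
            try:
                vel = estimate_velocity(sparse, path, t0=0,
                                        n_frames=config.kymo_n_frames,
                                        angle_step_deg=config.angle_step_deg)
                entry["velocity_um_s"] = abs(vel.velocity_um_s)
                entry["velocity_quality"] = vel.quality
                records.append({"timepoint": 0, "vessel_id": vid,
                                "quantity": "velocity",
                                "value": round(abs(vel.velocity_um_s), 3),
                                "units": "um/s"})
            except ValueError as e:
                entry["velocity_error"] = str(e)
                report.warnings.append(f"vessel {vid}: velocity failed ({e})")
        report.vessels.append(entry)
    report.add_stage("measure", time.perf_counter() - t,
                     n_vessels=len(centerlines))

    if out_dir is not None:
        write_results(records, out_dir / "results.csv", config=config)
        report.save(out_dir / "report.json")
        np.save(out_dir / "vessel_mask.npy", mask)
    return report
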