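"""End-to-end quantification runs driven by a serializable config.

A :class:`RunConfig` names the inputs (a TIFF stack or a simulation
spec), the threshold method, the calibration (a saved curve or a
single-anchor spec), the morphometry filters and the output directory;
:func:`run_pipeline` executes background correction -> projection /
per-plane segmentation -> ratios -> pH interpolation and writes tidy
CSVs plus a provenance sidecar. A persisted config re-executes to
identical outputs for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationCurve,
    build_calibration_anchored,
    build_calibration_full,
)
from .imaging import (
    PH_INDEP,
    ImageStack,
    ObjectFilters,
    background_correct,
    field_ratio,
    make_mask,
    object_ratios,
    records_to_frame,
    segment_objects,
    sum_project,
)
from .io import read_stack, write_results
from .spectroscopy import TitrationSeries
from .synthetic import default_config, simulate_stack

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one quantification run."""

    out_dir: str
    stack_path: str | None = None  # TIFF input; None => simulate
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    channel_map: dict | None = None  # role -> channel index
    pixel_size: float | None = None  # metadata override
    z_spacing: float | None = None
    threshold: object = "otsu"  # "otsu" | ["fixed", v] | ["percentile", p]
    calibration: object = None  # path to curve JSON, or anchor spec dict
    mode: str = "both"  # "field" | "object" | "both"
    split_rule: str = "saddle"
    filter_area: tuple = (10.0, 1500.0)
    filter_outer_radius: tuple = (0.0, 1000.0)
    filter_units: str = "calibrated"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def object_filters(self) -> ObjectFilters:
        return ObjectFilters(
            area=tuple(self.filter_area),
            outer_radius=tuple(self.filter_outer_radius),
            units=self.filter_units,
        )

    def threshold_method(self):
        if isinstance(self.threshold, str):
            return self.threshold
        kind, value = self.threshold
        return (kind, float(value))


@dataclass
class PipelineResult:
    out_dir: Path
    field: pd.DataFrame | None
    objects: pd.DataFrame | None
    discards: pd.DataFrame | None
    provenance: dict


def _load_calibration(spec, seed: int) -> CalibrationCurve | None:
    if spec is None:
        return None
    if isinstance(spec, (str, Path)):
        return CalibrationCurve.from_json(spec)
    spec = dict(spec)
    solution = TitrationSeries.from_csv(spec["solution_csv"])
    if "anchor_ratio" in spec:
        return build_calibration_anchored(
            float(spec["anchor_ratio"]), solution,
            anchor_ph=float(spec.get("anchor_ph", 5.0)),
        )
    return build_calibration_full(solution)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one quantification run and write its artifacts.

    Outputs land in ``config.out_dir`` only on success (work happens in
    a ``.partial`` staging directory that is atomically renamed), so a
    failed run leaves no partial final directory behind.
    """
    out_dir = Path(config.out_dir)
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        result = _run(config, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    result.out_dir = out_dir
    return result


def _run(config: RunConfig, staging: Path) -> PipelineResult:
    provenance: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }

    if config.stack_path is not None:
        stack = read_stack(
            config.stack_path, channel_map=config.channel_map,
            pixel_size=config.pixel_size, z_spacing=config.z_spacing,
            pixels_mode=config.filter_units == "pixel",
        )
        provenance["input"] = str(config.stack_path)
    else:
        sim = default_config(seed=config.seed, **config.simulate)
        stack, truth = simulate_stack(sim)
        truth.to_csv(staging / "ground_truth.csv")
        provenance["input"] = "simulated"
        provenance["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim).items()
            if k != "probe"
        }

    calibration = _load_calibration(config.calibration, config.seed)
    if calibration is not None:
        calibration.to_json(staging / "calibration.json")

    corrected = background_correct(stack)
    provenance["background_subtracted"] = corrected.meta["background_subtracted"]

    field_df = objects_df = discards_df = None
    method = config.threshold_method()

    if config.mode in ("field", "both"):
        projection = sum_project(corrected)
        mask = make_mask(projection.channel(PH_INDEP), method)
        res = field_ratio(projection, mask, calibration)
        provenance["field_threshold"] = mask.threshold
        field_df = pd.DataFrame(
            [{
                "ratio": res.ratio, "ph": res.ph, "ph_flag": res.ph_flag,
                "n_mask_pixels": res.n_mask_pixels,
                "intensity_ph_dep": res.intensity_ph_dep,
                "intensity_ph_indep": res.intensity_ph_indep,
                "threshold": res.threshold,
            }]
        )
        write_results(field_df, staging / "field.csv", {"stage": "field"})

    if config.mode in ("object", "both"):
        # one threshold for all planes, pooled over the whole corrected
        # reference stack: per-plane Otsu misbehaves on organelle-free
        # planes, where it splits the background histogram
        ref_stack = corrected.channel(PH_INDEP)
        if method == "otsu":
            pooled = float(make_mask(ref_stack.reshape(1, -1), "otsu").threshold)
        else:
            pooled = None
        all_records, all_discards, thresholds = [], [], []
        for p in range(stack.shape[0]):
            plane = corrected.channel(PH_INDEP)[p]
            if np.ptp(plane) == 0:
                continue
            seg = segment_objects(
                plane,
                pooled if pooled is not None else make_mask(plane, method),
                split_rule=config.split_rule,
                filters=config.object_filters(),
                pixel_size=stack.pixel_size,
                plane_index=p,
            )
            thresholds.append(seg.threshold)
            object_ratios(seg.records, corrected, calibration)
            all_records.extend(seg.records)
            all_discards.append(seg.discards)
        provenance["object_thresholds"] = thresholds
        objects_df = records_to_frame(all_records)
        discards_df = (
            pd.concat(all_discards, ignore_index=True)
            if all_discards else pd.DataFrame()
        )
        write_results(objects_df, staging / "objects.csv", {"stage": "object"})
        write_results(discards_df, staging / "discards.csv", {"stage": "discards"})

    (staging / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return PipelineResult(staging, field_df, objects_df, discards_df, provenance)
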