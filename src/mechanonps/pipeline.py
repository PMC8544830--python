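"""End-to-end workflow: (simulate) -> preprocess -> detect -> phenotype -> QC.

Every run is fully determined by (trace bytes or simulation seed, config);
the effective configuration is written next to the outputs and every stage
logs its parameters and counts, so results are auditable and byte-identical
across repeat runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .detect import DetectionConfig, DetectionResult, ThresholdConfig, detect_cells
from .geometry import DeviceGeometry, get_preset, load_geometry
from .phenotype import PhenotypeParams, phenotype_pipeline, records_to_dataframe
from .preprocess import PreprocessParams, Trace, preprocess_pipeline
from .simulate import (AcquisitionConfig, GroundTruthManifest,
                       PopulationParams, simulate_recording)

__all__ = ["RunConfig", "RunResult", "run_end_to_end", "process_trace"]

log = logging.getLogger("mechanonps")


@dataclass
class RunConfig:
    geometry: str = "AP-1060"            # preset name or path to a JSON file
    n_cells: int = 50
    seed: int = 0
    trace_path: str | None = None        # process an existing trace instead
    out_prefix: str | None = None
    population: PopulationParams = field(default_factory=PopulationParams)
    acquisition: AcquisitionConfig | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    log_level: str = "INFO"

    def resolve_geometry(self) -> DeviceGeometry:
        if not self.geometry:
            raise ValueError("config error: missing field 'geometry'")
        if Path(self.geometry).suffix == ".json":
            return load_geometry(self.geometry)
        return get_preset(self.geometry)

    def effective_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry_resolved"] = self.resolve_geometry().to_dict()
        return d


@dataclass
class RunResult:
    records: pd.DataFrame
    detection: DetectionResult
    trace: Trace
    manifest: GroundTruthManifest | None
    paths: dict[str, Path] = field(default_factory=dict)


def process_trace(trace: Trace, geometry: DeviceGeometry,
                  preprocess: PreprocessParams = PreprocessParams(),
                  detection: DetectionConfig = DetectionConfig(),
                  phenotype: PhenotypeParams = PhenotypeParams()
                  ) -> tuple[pd.DataFrame, DetectionResult]:
    """Preprocess -> detect -> phenotype one trace; returns records + windows."""
    normalized = preprocess_pipeline(trace, preprocess)
    log.info("preprocess: %d raw samples -> %d at %.1f Hz (filter=%d, ds=%d, "
             "asls lambda=%g p=%g iters=%d)", len(trace), len(normalized.samples),
             normalized.sample_rate_hz, preprocess.filter_width,
             preprocess.downsample_factor, preprocess.asls_lambda,
             preprocess.asls_p, preprocess.asls_iters)
    det = detect_cells(normalized, geometry, detection)
    n_rej = sum(1 for w in det.windows if w.status == "auto_rejected")
    log.info("detect: thresholds pore=%g contraction=%g; %d windows proposed, "
             "%d auto-rejected, %d accepted", detection.thresholds.pore_threshold,
             detection.thresholds.contraction_threshold, len(det.windows),
             n_rej, len(det.accepted))
    records = phenotype_pipeline(det.accepted, geometry, phenotype)
    df = records_to_dataframe(records)
    if len(df):
        log.info("phenotype: %d cells, %d flagged outlier, %d flagged erroneous",
                 len(df), int(df["statistical_outlier"].sum()),
                 int(df["erroneous"].sum()))
    return df, det


def run_end_to_end(config: RunConfig) -> RunResult:
    """Run the full pipeline per config, writing artifacts when requested."""
    logging.basicConfig(level=config.log_level)
    geometry = config.resolve_geometry()
    manifest = None
    if config.trace_path:
        trace = mio.read_trace(config.trace_path)
    else:
        acq = config.acquisition or AcquisitionConfig(seed=config.seed + 1)
        trace, manifest = simulate_recording(
            geometry, config.n_cells, seed=config.seed,
            params=config.population, acquisition=acq)
        log.info("simulate: %d cells (%d valid), %.1f s at %g Hz, seed %d",
                 len(manifest.cells), len(manifest.valid_cells),
                 trace.duration_s, trace.sample_rate_hz, config.seed)
    records, det = process_trace(trace, geometry, config.preprocess,
                                 config.detection, config.phenotype)
    paths: dict[str, Path] = {}
    if config.out_prefix:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths["records"] = mio.write_records(
            records, prefix.with_name(prefix.name + "_records.csv"))
        det.to_table().to_csv(
            prefix.with_name(prefix.name + "_windows.csv"), index=False)
        paths["windows"] = prefix.with_name(prefix.name + "_windows.csv")
        if manifest is not None:
            csv_p, json_p = mio.write_manifest(manifest, prefix)
            paths["manifest_csv"], paths["manifest_json"] = csv_p, json_p
        cfg_path = prefix.with_name(prefix.name + "_config.json")
        cfg_path.write_text(json.dumps(config.effective_dict(), indent=2,
                                       default=str))
        paths["config"] = cfg_path
    return RunResult(records=records, detection=det, trace=trace,
                     manifest=manifest, paths=paths)
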