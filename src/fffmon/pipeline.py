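"""End-to-end orchestration: alignment, cleaning, phase setting, feature
extraction and multivariate analysis, with all artifacts written to disk.

The configuration is a single validated document (JSON or YAML); unknown
keys are rejected so a typo cannot silently disable a stage.  Every run is
deterministic given the configuration and seed, and a run log records the
configuration hash so results stay auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import cleaning as _cleaning
from . import io_align
from .batch import Batch
from .features import (
    FeatureMatrix,
    build_feature_matrix,
    drop_zero_variance,
    impute_missing,
    scale_features,
    specs_from_segmentations,
)
from .phase_rules import apply_ruleset, default_lp_ruleset, load_ruleset
from .phase_step import StepConfig, detect_step_phases
from .robpca import ROBPCA, ClassicalPCADiagnostics
from .synthetic import (
    CampaignSpec,
    default_contaminations,
    default_feature_specs,
    default_step_config,
    generate_campaign,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class SyntheticSource(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_lots: int = 58
    contaminated: bool = True
    noise_scale: float = 1.0


class FileSources(BaseModel):
    model_config = ConfigDict(extra="forbid")
    qdb_path: str
    lyo_path: str
    sf_path: str | None = None


class CleaningSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sf2_terminal_slope_threshold: float = 1e-3  # bar per second
    sf3_spike_slope_threshold: float | None = None  # None: 10 x noise / dt
    spike_max_duration: float = 600.0


class StepSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    signals: list[str] = Field(
        default_factory=lambda: ["LP1", "LP2", "LP3", "LP5", "LP6", "LP7", "SF1"]
    )
    lookahead: int = 1
    threshold_step: float = 1.5
    max_iterations: int = 20
    slope_duration_bounds: tuple[float, float] = (180.0, 7200.0)
    plateau_duration_bounds: tuple[float, float] = (600.0, 1e9)


class RobpcaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int | None = None
    variance_target: float = 0.80
    alpha: float = 0.75
    quantile: float = 0.975
    compare_classical: bool = True


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    synthetic: SyntheticSource | None = None
    sources: FileSources | None = None
    ruleset_path: str | None = None  # None: bundled lyophilization rules
    cleaning: CleaningSettings = Field(default_factory=CleaningSettings)
    step: StepSettings = Field(default_factory=StepSettings)
    scaling: str = "robust"
    robpca: RobpcaSettings = Field(default_factory=RobpcaSettings)
    seed: int = 0
    outdir: str = "fffmon_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_batches(config: PipelineConfig) -> list[Batch]:
    if (config.synthetic is None) == (config.sources is None):
        raise ValueError("configure exactly one of 'synthetic' or 'sources'")
    if config.synthetic is not None:
        spec = CampaignSpec(
            n_lots=config.synthetic.n_lots,
            noise_scale=config.synthetic.noise_scale,
            contaminations=(
                default_contaminations(config.synthetic.n_lots)
                if config.synthetic.contaminated
                else []
            ),
            master_seed=config.seed,
        )
        batches, stream, _ = generate_campaign(spec)
        records = [b.qdb for b in batches]
    else:
        src = config.sources
        records = io_align.parse_qdb_table(src.qdb_path)
        lyo, _ = io_align.parse_timeseries_table(src.lyo_path, layout="long")
        lyo_by_lot: dict[str, list] = {}
        for ts in lyo:
            lyo_by_lot.setdefault(ts.lot_id, []).append(ts)
        batches = io_align.assemble_batches(records, lyo_by_lot)
        stream = None
        if src.sf_path:
            stream, _ = io_align.parse_timeseries_table(src.sf_path, layout="long")

    if stream:
        segments, report = io_align.segment_stream_by_intervals(stream, records, "sterile_filtration")
        for batch in batches:
            for ts in segments.get(batch.lot_id, []):
                batch.add_series(ts)
        logger.info("stream segmentation: %d samples unassigned", report.unassigned_samples)
    return batches


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the five-step monitoring workflow and write all artifacts.

    Returns the artifact directory.  Stage failures carry the stage name and
    lot context; a failing lot is flagged, not fatal, wherever the analysis
    can continue without it.
    """
    logger.info("step 1/5: data alignment")
    batches = _load_batches(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_align.write_batches(batches, outdir)

    logger.info("step 2/5: data cleaning")
    cleaning_reports: dict[str, dict] = {}
    ccfg_sf2 = _cleaning.CleaningConfig(
        terminal_slope_threshold=config.cleaning.sf2_terminal_slope_threshold
    )
    ccfg_sf3 = _cleaning.CleaningConfig(
        spike_slope_threshold=config.cleaning.sf3_spike_slope_threshold,
        spike_max_duration=config.cleaning.spike_max_duration,
    )
    for batch in batches:
        reports = {}
        if "SF2" in batch.series:
            batch.series["SF2"], rep = _cleaning.remove_terminal_slope(batch.series["SF2"], ccfg_sf2)
            reports["SF2"] = rep.to_dict()
        if "SF3" in batch.series:
            batch.series["SF3"], rep = _cleaning.remove_spikes(batch.series["SF3"], ccfg_sf3)
            reports["SF3"] = rep.to_dict()
        if reports:
            cleaning_reports[batch.lot_id] = reports
    (outdir / "cleaning_reports.json").write_text(json.dumps(cleaning_reports, indent=2))

    logger.info("step 3/5: dynamic phase setting")
    step_cfg_base = default_step_config()
    step_cfg = StepConfig(
        lookahead=config.step.lookahead,
        duration_bounds={
            "slope": tuple(config.step.slope_duration_bounds),
            "plateau": tuple(config.step.plateau_duration_bounds),
        },
        threshold_step=config.step.threshold_step,
        max_iterations=config.step.max_iterations,
    )
    segmentations: dict[str, dict] = {}
    for batch in batches:
        segmentations[batch.lot_id] = {}
        for signal in config.step.signals:
            if signal not in batch.series:
                logger.info("lot %s: signal %s absent, skipped", batch.lot_id, signal)
                continue
            try:
                segmentations[batch.lot_id][signal] = detect_step_phases(batch.series[signal], step_cfg)
            except ValueError as exc:
                logger.warning("lot %s / %s: step segmentation failed: %s", batch.lot_id, signal, exc)

    ruleset = load_ruleset(config.ruleset_path) if config.ruleset_path else default_lp_ruleset()
    rule_phases: dict[str, list] = {}
    rule_failures: dict[str, dict] = {}
    for batch in batches:
        result = apply_ruleset(ruleset, batch)
        rule_phases[batch.lot_id] = result.phases
        if result.failures:
            rule_failures[batch.lot_id] = result.failures
            logger.warning("lot %s: rule phases incomplete: %s", batch.lot_id, result.failures)
    _write_segmentations(outdir, segmentations, rule_phases)

    logger.info("step 4/5: feature extraction")
    if config.synthetic is not None:
        specs = default_feature_specs()
    else:
        specs = specs_from_segmentations(segmentations, rule_phases)
    fm = build_feature_matrix(batches, segmentations, rule_phases, specs)
    fm.values.to_csv(outdir / "feature_matrix.csv")
    (outdir / "feature_provenance.json").write_text(json.dumps(fm.provenance, indent=2))
    fm_filtered, removed = drop_zero_variance(fm)
    fm_complete, dropped_missing = impute_missing(fm_filtered)
    fm_scaled, scale_params = scale_features(fm_complete, method=config.scaling)

    logger.info("step 5/5: multivariate analysis")
    X = fm_scaled.to_numpy()
    model = ROBPCA(
        n_components=config.robpca.k,
        variance_target=config.robpca.variance_target,
        alpha=config.robpca.alpha,
        quantile=config.robpca.quantile,
        random_state=config.seed,
    ).fit(X)
    outlier_map = pd.DataFrame(
        {
            "lot_id": fm_scaled.lot_ids,
            "score_distance": model.sd_,
            "orthogonal_distance": model.od_,
            "quadrant": model.quadrants_,
        }
    )
    outlier_map.to_csv(outdir / "outlier_map.csv", index=False)
    contrib = pd.DataFrame(
        model.score_contributions(X), index=fm_scaled.lot_ids, columns=fm_scaled.values.columns
    )
    contrib.to_csv(outdir / "score_contributions.csv")

    cpca_payload = None
    if config.robpca.compare_classical:
        cpca = ClassicalPCADiagnostics(n_components=model.n_components_).fit(X)
        pd.DataFrame(
            {
                "lot_id": fm_scaled.lot_ids,
                "hotelling_t2": cpca.t2_,
                "dmodx": cpca.dmodx_,
            }
        ).to_csv(outdir / "cpca_diagnostics.csv", index=False)
        cpca_payload = {
            "t2_limit": cpca.t2_limit_,
            "t2_median": cpca.t2_median_,
            "dmodx_limit": cpca.dmodx_limit_,
        }

    model_payload = {
        "center": model.center_.tolist(),
        "loadings": model.components_.tolist(),
        "eigenvalues": model.eigenvalues_.tolist(),
        "n_components": model.n_components_,
        "explained_variance_fraction": model.explained_variance_fraction_,
        "sd_cutoff": model.sd_cutoff_,
        "od_cutoff": model.od_cutoff_,
        "quantile": config.robpca.quantile,
        "alpha": config.robpca.alpha,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "columns": list(fm_scaled.values.columns),
        "scaling": {
            "method": config.scaling,
            "center": scale_params["center"].to_dict(),
            "scale": scale_params["scale"].to_dict(),
        },
        "zero_variance_removed": removed,
        "high_missingness_dropped": dropped_missing,
        "cpca": cpca_payload,
    }
    (outdir / "robpca_model.json").write_text(json.dumps(model_payload, indent=2))

    run_log = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_lots": len(batches),
        "n_features_raw": fm.shape[1],
        "n_features_modelled": fm_scaled.shape[1],
        "n_components": model.n_components_,
        "explained_variance_fraction": model.explained_variance_fraction_,
        "flagged_lots": {
            lot: quad
            for lot, quad in zip(fm_scaled.lot_ids, model.quadrants_)
            if quad != "regular"
        },
        "rule_failures": rule_failures,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    logger.info(
        "done: %d lots, %d features, k=%d, %d flagged",
        len(batches), fm_scaled.shape[1], model.n_components_, len(run_log["flagged_lots"]),
    )
    return outdir


def _write_segmentations(outdir: Path, segmentations: dict, rule_phases: dict) -> None:
    rows = []
    for lot, per_signal in segmentations.items():
        for signal, seg in per_signal.items():
            for phase in seg.phases:
                rows.append(
                    {
                        "lot_id": lot, "signal": signal, "label": phase.label,
                        "kind": phase.kind, "start_time": phase.start_time,
                        "end_time": phase.end_time,
                    }
                )
    for lot, phases in rule_phases.items():
        for phase in phases:
            rows.append(
                {
                    "lot_id": lot, "signal": phase.signal_name or "", "label": phase.label,
                    "kind": phase.kind, "start_time": phase.start_time,
                    "end_time": phase.end_time,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "segmentations.csv", index=False)
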