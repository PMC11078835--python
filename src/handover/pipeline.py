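"""End-to-end orchestration: simulate -> segment -> features -> stats.

A single master seed drives every stochastic stage. The pipeline streams
trials (recordings are discarded once their features are extracted), writes
plain-file stage outputs (features.csv, anova.csv, posthoc.csv) and a
manifest with the configuration snapshot and bookkeeping counts, so a run is
fully reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from handover.events import PipelineConfig, TrialRejected, segment_trial
from handover.features import TrialFeatures, extract_features
from handover.preprocessing import FilterSpec, preprocess_recording
from handover.simulate import GroundTruth, SimulatorConfig, simulate_experiment
from handover.trial_io import TrialRecording

__all__ = [
    "PipelineSettings",
    "RunManifest",
    "run_pipeline",
    "features_to_frame",
    "ground_truth_to_frame",
]

logger = logging.getLogger("handover.pipeline")

FEATURE_COLUMNS = [
    "dyad_id",
    "block",
    "trial_in_block",
    "giver_id",
    "receiver_id",
    "size",
    "weight",
    "lift_delay",
    "max_lift_velocity",
    "giver_pgfr",
    "receiver_pgfr",
    "receiver_pgfr_fallback_used",
    "giver_pgfr_fallback_used",
]


@dataclass
class PipelineSettings:
    """Configuration of a full pipeline run."""

    n_dyads: int = 20
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    detection: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        return {
            "n_dyads": self.n_dyads,
            "simulator": self.simulator.to_dict(),
            "filter": dataclasses.asdict(self.filter),
            "detection": dataclasses.asdict(self.detection),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineSettings":
        return cls(
            n_dyads=int(d.get("n_dyads", 20)),
            simulator=SimulatorConfig.from_dict(d.get("simulator", {})),
            filter=FilterSpec(**d.get("filter", {})),
            detection=PipelineConfig(**d.get("detection", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineSettings":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    """Bookkeeping of one pipeline run: counts are consistent by
    construction (generated = analyzed + rejected)."""

    seed: int
    settings: dict
    n_trials_generated: int
    n_trials_analyzed: int
    n_trials_rejected: int
    n_receiver_fallback: int
    rejections: list
    outputs: dict
    version: str

    def __post_init__(self) -> None:
        if self.n_trials_generated != self.n_trials_analyzed + self.n_trials_rejected:
            raise ValueError("inconsistent trial counts in manifest")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def features_to_frame(rows: list[TrialFeatures]) -> pd.DataFrame:
    """Long-format feature table: one row per analyzed trial."""
    recs = []
    for f in rows:
        c = f.condition
        recs.append(
            {
                "dyad_id": c.dyad_id,
                "block": c.block,
                "trial_in_block": c.trial_in_block,
                "giver_id": c.giver_id,
                "receiver_id": c.receiver_id,
                "size": c.size.value,
                "weight": c.weight.value,
                "lift_delay": f.lift_delay,
                "max_lift_velocity": f.max_lift_velocity,
                "giver_pgfr": f.giver_pgfr,
                "receiver_pgfr": f.receiver_pgfr,
                "receiver_pgfr_fallback_used": f.receiver_pgfr_fallback_used,
                "giver_pgfr_fallback_used": f.giver_pgfr_fallback_used,
            }
        )
    return pd.DataFrame(recs, columns=FEATURE_COLUMNS)


def ground_truth_to_frame(
    pairs: list[tuple[TrialRecording, GroundTruth]]
) -> pd.DataFrame:
    """Tabulate ground truth next to trial identifiers."""
    recs = []
    for rec, gt in pairs:
        c = rec.meta.condition
        row = {
            "dyad_id": c.dyad_id,
            "block": c.block,
            "trial_in_block": c.trial_in_block,
            "size": c.size.value,
            "weight": c.weight.value,
        }
        row.update(dataclasses.asdict(gt))
        recs.append(row)
    return pd.DataFrame(recs)


def process_trial(
    rec: TrialRecording,
    settings: PipelineSettings,
) -> TrialFeatures:
    """Filter, segment and featurize one trial (raises TrialRejected)."""
    filtered = preprocess_recording(rec, settings.filter)
    events, phases = segment_trial(filtered, settings.detection)
    return extract_features(filtered, events, phases, settings.detection)


def run_pipeline(
    settings: PipelineSettings | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "pipeline_out",
) -> RunManifest:
    """Execute all stages and write features.csv, anova.csv, posthoc.csv and
    manifest.json under ``out_dir``. Deterministic under a fixed seed."""
    if settings is None:
        settings = PipelineSettings()
    elif isinstance(settings, (str, Path)):
        settings = PipelineSettings.from_yaml(settings)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows: list[TrialFeatures] = []
    rejections: list[dict] = []
    n_gen = 0
    for rec, gt in simulate_experiment(settings.n_dyads, settings.simulator, seed):
        n_gen += 1
        c = rec.meta.condition
        try:
            rows.append(process_trial(rec, settings))
        except TrialRejected as err:
            rejections.append(
                {
                    "dyad_id": c.dyad_id,
                    "block": c.block,
                    "trial_in_block": c.trial_in_block,
                    "reason": err.reason,
                }
            )
            logger.warning(
                "rejected dyad %s block %d trial %d: %s",
                c.dyad_id,
                c.block,
                c.trial_in_block,
                err.reason,
            )
    features = features_to_frame(rows)
    features_path = out / "features.csv"
    features.to_csv(features_path, index=False)
    logger.info(
        "simulated %d trials (%d analyzed, %d rejected)",
        n_gen,
        len(rows),
        len(rejections),
    )

    outputs = {"features": str(features_path)}
    if len(rows):
        from handover.stats import analyze_features

        anova, posthoc, _ = analyze_features(features)
        anova_path = out / "anova.csv"
        posthoc_path = out / "posthoc.csv"
        anova.to_csv(anova_path, index=False)
        posthoc.to_csv(posthoc_path, index=False)
        outputs["anova"] = str(anova_path)
        outputs["posthoc"] = str(posthoc_path)

    from handover import __version__

    manifest = RunManifest(
        seed=int(seed),
        settings=settings.to_dict(),
        n_trials_generated=n_gen,
        n_trials_analyzed=len(rows),
        n_trials_rejected=len(rejections),
        n_receiver_fallback=int(features["receiver_pgfr_fallback_used"].sum())
        if len(rows)
        else 0,
        rejections=rejections,
        outputs=outputs,
        version=__version__,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
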