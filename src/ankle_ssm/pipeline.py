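"""End-to-end analysis pipeline.

read TPS + metadata -> mirror/validate -> generalized Procrustes -> shape
model -> mode retention -> standardized scores -> descriptive table ->
minimally / fully adjusted injury odds-ratio tables -> race model ->
(optional) repeatability report -> mode figures -> run manifest.

Every stage logs counts in/out; any stage error aborts with the stage
name.  Given the same inputs and configuration the bundle is
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .association import ADJUSTMENT_COVARIATES, run_injury_models, run_race_model
from .io_landmarks import (
    build_dataset,
    default_scheme,
    read_metadata_table,
    read_tps,
    summarize_cohort,
)
from .procrustes import align_to_frame, generalized_procrustes
from .repeatability import repeatability_report
from .shape_model import ShapePCA, score_shapes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable).

    Retention thresholds, score standardization, adjustment covariates,
    repeatability thresholds and the figure request all default to the
    analysis conventions this package implements: 80% cumulative / 1%
    per-mode retention, per-SD scores, six adjustment covariates,
    1 / 1.5 / 2 mm thresholds, +/-2 SD outlines for the leading modes.
    """

    tps_path: str = ""
    metadata_path: str = ""
    repeat_tps_path: str | None = None
    output_dir: str = "ankle_ssm_output"
    cum_threshold: float = 0.80
    min_fraction: float = 0.01
    standardize_scores: bool = True
    covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES
    figure_modes: tuple[int, ...] = (1, 2)   # 1-based mode numbers
    figure_k_sd: tuple[float, ...] = (2.0, 2.0)
    ci_z: float = 1.96
    repeat_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0)
    metadata_delimiter: str = ","
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cum_threshold <= 1 or not 0 < self.min_fraction <= 1:
            raise ValueError("retention thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        for key in ("covariates", "figure_modes", "figure_k_sd", "repeat_thresholds"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a manifest of bundle file paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, str] = {}
    scheme = default_scheme()

    # --- ingest -----------------------------------------------------------
    read = _stage("read_inputs")(lambda: (
        read_tps(config.tps_path, scheme),
        read_metadata_table(config.metadata_path, config.metadata_delimiter),
    ))
    configs, metadata = read()
    logger.info("read %d configurations, %d metadata rows", len(configs), len(metadata))

    dataset = _stage("build_dataset")(build_dataset)(configs, metadata, scheme)
    n_left = sum(1 for m in dataset.metadata.values() if m.side == "left")
    logger.info("dataset: %d ankles kept (%d mirrored from left), %d excluded",
                len(dataset), n_left, len(configs) - len(dataset))

    # --- descriptives -----------------------------------------------------
    table1 = _stage("descriptives")(summarize_cohort)(dataset)
    table1.to_csv(out / "table1_descriptives.csv", index=False)
    bundle["table1"] = str(out / "table1_descriptives.csv")

    # --- alignment --------------------------------------------------------
    aligned = _stage("generalized_procrustes")(generalized_procrustes)(dataset)
    align_log = {
        "n_shapes": aligned.n_shapes,
        "iterations": aligned.iterations,
        "final_change": aligned.final_change,
        "procrustes_ss": aligned.ss_history,
    }
    with open(out / "alignment_log.json", "w") as fh:
        json.dump(align_log, fh, indent=2)
    bundle["alignment_log"] = str(out / "alignment_log.json")

    # --- shape model ------------------------------------------------------
    results = _stage("shape_model")(
        lambda: ShapePCA(aligned, scheme).fit(
            cum_threshold=config.cum_threshold,
            min_fraction=config.min_fraction,
            standardize=config.standardize_scores,
        )
    )()
    results.model.to_json(out / "shape_model.json")
    bundle["shape_model"] = str(out / "shape_model.json")
    variance_table = results.summary()
    variance_table.to_csv(out / "variance_table.csv", index=False)
    bundle["variance_table"] = str(out / "variance_table.csv")
    retained_1based = [j + 1 for j in results.retained]
    logger.info("retained %d modes (cumulative %.1f%%)", len(retained_1based),
                100 * results.model.fractions[results.retained].sum())

    scores_frame = results.scores.frame()
    scores_frame.insert(0, "ankle_id", aligned.ankle_ids)
    scores_frame.to_csv(out / "mode_scores.csv", index=False)
    bundle["mode_scores"] = str(out / "mode_scores.csv")

    # --- association ------------------------------------------------------
    md = dataset.metadata_frame()
    or1, or2 = _stage("injury_models")(run_injury_models)(results.scores, md)
    or_tables = pd.concat([or1, or2], ignore_index=True)
    or_tables.to_csv(out / "or_tables.csv", index=False)
    bundle["or_tables"] = str(out / "or_tables.csv")
    race_table = _stage("race_model")(run_race_model)(results.scores, md)
    race_table.to_csv(out / "race_model.csv", index=False)
    bundle["race_model"] = str(out / "race_model.csv")

    # --- repeatability ----------------------------------------------------
    if config.repeat_tps_path:
        def _repeat():
            repeat_configs = read_tps(config.repeat_tps_path, scheme)
            sides = {aid: m.side for aid, m in dataset.metadata.items()}
            first, second = [], []
            by_id = {c.ankle_id: c for c in configs}
            for rc in repeat_configs:
                if rc.ankle_id in by_id:
                    first.append(by_id[rc.ankle_id])
                    second.append(rc)
            report = repeatability_report(
                first, second, thresholds=config.repeat_thresholds
            )
            # ICC of mode-1 scores between readings, in the fitted frame
            from dataclasses import replace as _replace

            from .io_landmarks import mirror_left_to_right
            def frame_scores(cfgs):
                fixed = [
                    mirror_left_to_right(_replace(c, side="left"))
                    if sides.get(c.ankle_id) == "left" else c
                    for c in cfgs
                ]
                mat = align_to_frame(results.model.mean, fixed)
                return score_shapes(results.model, mat,
                                    standardize=False, modes=[0]).scores[:, 0]
            from .repeatability import icc_absolute_agreement
            icc, ci = icc_absolute_agreement(frame_scores(first), frame_scores(second))
            report.icc, report.icc_ci = icc, ci
            return report
        report = _stage("repeatability")(_repeat)()
        report.frame().to_csv(out / "repeatability.csv", index=False)
        report.distances.to_csv(out / "repeatability_distances.csv", index=False)
        bundle["repeatability"] = str(out / "repeatability.csv")

    # --- figures ----------------------------------------------------------
    def _figures():
        modes0 = [m - 1 for m in config.figure_modes]
        bad = [m for m in modes0 if not 0 <= m < results.model.n_modes]
        if bad:
            raise ValueError(f"unknown figure modes {[m + 1 for m in bad]}")
        path = out / "mode_figures.svg"
        results.plot_modes(modes0, list(config.figure_k_sd), path=path)
        return str(path)
    bundle["figures"] = _stage("figures")(_figures)()

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "retained_modes": retained_1based,
        "n_ankles": len(dataset),
        "n_participants": md["participant_id"].nunique(),
        "bundle": bundle,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = str(out / "manifest.json")
    return manifest
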