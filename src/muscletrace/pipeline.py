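"""Config-driven pipeline runs with a reproducibility manifest.

A :class:`RunConfig` (usually loaded from YAML) selects stages and carries
every tunable parameter; unknown keys are rejected up front, and all input
files are checked before any computation starts. :func:`run_pipeline`
executes the selected stages and writes a :class:`RunManifest` (tool version,
config hash, input checksums, per-stage outputs) atomically at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import io as mio
from .panel import default_panel
from .qpcr import (
    compute_lod,
    ct_to_expression,
    filter_cells,
    normalize_to_controls,
    spearman_correlogram,
)
from .rnascope import ScoreBins, marker_crosstab
from .tracks import compare_conditions, summarize_tracks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


class QpcrStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ct_path: str
    panel_path: str | None = None
    orientation: Literal["genes_by_cells", "cells_by_genes"] = "genes_by_cells"
    sentinel: float = 999.0
    min_controls: int = 4
    min_interest: int = 2
    zero_as_missing: bool = True
    min_pairs: int = 3
    offset_on_filtered: bool = True  # compute the offset on the post-filter matrix


class TracksStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tracks_path: str
    group_by: str = "condition"
    frame_interval_min: float = 15.0
    scale_um_per_px: float = 1.0


class RnascopeStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dots_path: str
    score_scale: Literal["0-4", "0-3"] = "0-4"
    round_ndigits: int = 0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str
    seed: int = 0
    qpcr: QpcrStageConfig | None = None
    tracks: TracksStageConfig | None = None
    rnascope: RnascopeStageConfig | None = None


class RunManifest(BaseModel):
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    outputs: dict[str, list[str]]
    started: str
    finished: str


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(config: RunConfig) -> list[Path]:
    paths = []
    if config.qpcr:
        paths.append(Path(config.qpcr.ct_path))
        if config.qpcr.panel_path:
            paths.append(Path(config.qpcr.panel_path))
    if config.tracks:
        paths.append(Path(config.tracks.tracks_path))
    if config.rnascope:
        paths.append(Path(config.rnascope.dots_path))
    return paths


def _run_qpcr(cfg: QpcrStageConfig, outdir: Path) -> list[str]:
    panel = mio.read_panel_yaml(cfg.panel_path) if cfg.panel_path else default_panel()
    ct = mio.read_ct_csv(
        cfg.ct_path, panel=panel, orientation=cfg.orientation, sentinel=cfg.sentinel
    )
    lod = compute_lod(ct)
    logger.info("qpcr: LOD = %d cycles", lod.value)
    expr = ct_to_expression(ct, lod)
    report = filter_cells(expr, min_controls=cfg.min_controls, min_interest=cfg.min_interest)
    logger.info("qpcr: %d/%d cells retained", report.n_retained, report.n_input)
    kept = expr.subset_cells(report.retained_cells) if cfg.offset_on_filtered else expr
    normalized = normalize_to_controls(kept)
    logger.info("qpcr: normalization offset = %.6g Log2ex", normalized.offset)
    corr = spearman_correlogram(
        normalized,
        zero_as_missing=cfg.zero_as_missing,
        min_pairs=cfg.min_pairs,
        genes=[g for g in panel.interest_genes if g in normalized.genes],
    )
    outputs = []
    for name, writer in (
        ("expression.csv", lambda p: mio.write_expression_csv(expr, p)),
        ("expression_normalized.csv", lambda p: mio.write_expression_csv(normalized, p)),
        ("filter_report.csv", lambda p: mio.write_filter_report_csv(report, p)),
    ):
        writer(outdir / name)
        outputs.append(name)
    mio.write_correlation_csvs(corr, outdir)
    outputs += ["rho.csv", "pval.csv", "n_pairs.csv"]
    return outputs


def _run_tracks(cfg: TracksStageConfig, outdir: Path) -> list[str]:
    import pandas as pd

    df = pd.read_csv(cfg.tracks_path)
    tracks = mio.read_tracks_csv(
        cfg.tracks_path,
        frame_interval_min=cfg.frame_interval_min,
        scale_um_per_px=cfg.scale_um_per_px,
    )
    metrics = summarize_tracks(tracks)
    metrics.to_csv(outdir / "track_metrics.csv")
    outputs = ["track_metrics.csv"]
    if cfg.group_by in df.columns and df[cfg.group_by].nunique() == 2:
        groups = df.drop_duplicates("track_id").set_index("track_id")[cfg.group_by]
        groups.index = groups.index.map(str)
        comparisons = compare_conditions(metrics, groups.loc[metrics.index])
        comparisons.to_csv(outdir / "group_comparisons.csv")
        outputs.append("group_comparisons.csv")
    return outputs


def _run_rnascope(cfg: RnascopeStageConfig, outdir: Path) -> list[str]:
    import pandas as pd

    records = mio.read_dots_csv(cfg.dots_path)
    bins = ScoreBins(cluster_is_own_score=cfg.score_scale == "0-4")
    tab = marker_crosstab(records, bins)
    tab.counts.to_csv(outdir / "crosstab.csv")
    pd.DataFrame([tab.rounded(cfg.round_ndigits) | {"n_total": tab.n_total}]).to_csv(
        outdir / "percentages.csv", index=False
    )
    return ["crosstab.csv", "percentages.csv"]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages; fail before any computation on missing inputs."""
    started = datetime.now(timezone.utc).isoformat()
    inputs = _input_paths(config)
    if not inputs:
        raise ValueError("no stage selected in configuration")
    missing = [str(p) for p in inputs if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    checksums = {str(p): _sha256(p) for p in inputs}

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    if config.qpcr:
        outputs["qpcr"] = _run_qpcr(config.qpcr, outdir)
    if config.tracks:
        outputs["tracks"] = _run_tracks(config.tracks, outdir)
    if config.rnascope:
        outputs["rnascope"] = _run_rnascope(config.rnascope, outdir)

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        input_checksums=checksums,
        outputs=outputs,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    # atomic manifest write
    fd, tmp = tempfile.mkstemp(dir=outdir, suffix=".manifest.tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(manifest.model_dump_json(indent=2))
    os.replace(tmp, outdir / "manifest.json")
    return manifest
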