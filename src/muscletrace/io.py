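"""Readers and writers for the pipeline's CSV/YAML formats.

Ct matrices are CSV/TSV with a header row of cell ids and a first column of
gene names (genes as rows by default; ``orientation="cells_by_genes"``
transposes on read). No-amplification wells carry the instrument sentinel
(999 by default), "Undetermined", or are blank. All output CSV uses "." as
the decimal separator and full float precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import GenePanel
from .qpcr import CorrelationResult, CtMatrix, ExpressionMatrix, FilterReport
from .rnascope import DotRecord
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "read_ct_csv",
    "write_ct_csv",
    "read_panel_yaml",
    "write_panel_yaml",
    "read_tracks_csv",
    "read_dots_csv",
    "write_expression_csv",
    "write_correlation_csvs",
    "write_filter_report_csv",
]

FAIL_STRINGS = {"undetermined", "fail", "999", "nan", ""}


def read_ct_csv(
    path: str | Path,
    panel: GenePanel | None = None,
    orientation: str = "genes_by_cells",
    sentinel: float = 999.0,
    sep: str | None = None,
) -> CtMatrix:
    """Read a Ct matrix; sentinel/blank/"Undetermined" wells become failed."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path) as fh:
        header = [h.strip().strip('"') for h in fh.readline().rstrip("\n").split(sep)][1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate cell ids in header: {dup}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = header  # undo pandas' dedup-mangling guard; names validated above
    if orientation == "cells_by_genes":
        raw = raw.T
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"duplicate cell ids: {dup}")

    values = np.full(raw.shape, np.nan)
    fail = np.zeros(raw.shape, dtype=bool)
    for i, gene in enumerate(raw.index):
        for j, cell in enumerate(raw.columns):
            cell_str = str(raw.iat[i, j]).strip()
            if cell_str.lower() in FAIL_STRINGS:
                fail[i, j] = True
                continue
            try:
                v = float(cell_str)
            except ValueError:
                raise ValueError(
                    f"non-numeric, non-sentinel value {cell_str!r} at gene {gene!r}, "
                    f"cell {cell!r}"
                ) from None
            if v >= sentinel:
                fail[i, j] = True
            else:
                values[i, j] = v
    idx = pd.Index(raw.index, name="gene")
    cols = pd.Index(raw.columns, name="cell_id")
    return CtMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        fail_mask=pd.DataFrame(fail, index=idx, columns=cols),
        panel=panel,
        metadata={"source": str(path), "sentinel": sentinel},
    )


def write_ct_csv(ct: CtMatrix, path: str | Path, sentinel: float = 999.0) -> None:
    """Write a Ct matrix; failed wells are written as the sentinel."""
    out = ct.values.where(~ct.fail_mask, sentinel)
    out.to_csv(path)


def read_panel_yaml(path: str | Path) -> GenePanel:
    """Gene roles from a YAML sidecar with control/interest/exclusion lists."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    unknown = set(spec) - {"controls", "interest", "exclusion", "normalizers"}
    if unknown:
        raise ValueError(f"unknown panel keys: {sorted(unknown)}")
    return GenePanel.from_role_lists(
        controls=spec.get("controls", ()),
        interest=spec.get("interest", ()),
        exclusion=spec.get("exclusion", ()),
        normalizers=spec.get("normalizers"),
    )


def write_panel_yaml(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "controls": list(panel.control_genes),
                "interest": list(panel.interest_genes),
                "exclusion": list(panel.exclusion_genes),
                "normalizers": list(panel.normalizer_genes),
            },
            fh,
            sort_keys=False,
        )


DEFAULT_TRACK_COLUMNS = {"track_id": "track_id", "frame": "frame", "x": "x", "y": "y"}


def read_tracks_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    frame_interval_min: float = 15.0,
    scale_um_per_px: float = 1.0,
) -> list[Track]:
    """Tracks from a tidy CSV; rows grouped by track id and sorted by frame.

    Coordinates are multiplied by ``scale_um_per_px``. Single-point tracks
    are logged and dropped; duplicate (track, frame) rows are an error.
    """
    cols = dict(DEFAULT_TRACK_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing track columns {missing} in {path}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        pairs = df.loc[dup, ["track_id", "frame"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (track, frame) rows: {pairs[:5]}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            logger.warning("track %r has a single point; dropped", tid)
            continue
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(),
                x=grp["x"].to_numpy(dtype=float) * scale_um_per_px,
                y=grp["y"].to_numpy(dtype=float) * scale_um_per_px,
                frame_interval_min=frame_interval_min,
            )
        )
    return tracks


def read_dots_csv(path: str | Path) -> list[DotRecord]:
    """Dot records from CSV columns cell_id, dots, cluster, marker[, section, embryo]."""
    df = pd.read_csv(path)
    required = {"cell_id", "dots", "cluster", "marker"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing dot-record columns: {sorted(missing)}")
    return [
        DotRecord(
            cell_id=str(r.cell_id),
            dot_count=int(r.dots),
            has_big_cluster=bool(r.cluster),
            marker_positive=bool(r.marker),
            section_id=str(r.section) if "section" in df.columns else None,
            embryo_id=str(r.embryo) if "embryo" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def write_expression_csv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path)


def write_filter_report_csv(report: FilterReport, path: str | Path) -> None:
    report.to_frame().to_csv(path)


def write_correlation_csvs(result: CorrelationResult, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    result.rho.to_csv(outdir / f"{prefix}rho.csv")
    result.pval.to_csv(outdir / f"{prefix}pval.csv")
    result.n_pairs.to_csv(outdir / f"{prefix}n_pairs.csv")
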