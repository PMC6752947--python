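"""Ordinal scoring of single-molecule in situ (RNAscope) dot counts.

Transcript abundance per cell is summarized as an ordinal score from the
number of chromogenic dots counted in the cell: 0 dots -> score 0, 1-3 dots
-> 1, 4-9 -> 2, 10 or more -> 3, and a "big cluster" (dots too dense to
resolve) -> the top score. Two score scales are supported: the default 0-4
scale puts big clusters in their own top bin (4); the compact 0-3 scale folds
them into 3.

Scores are cross-tabulated against a differentiation-marker status (e.g.
Myod/Myog nuclear staining) to ask whether transcript levels track the
undifferentiated state; a generic per-compartment reporter tally
(:func:`chimerism_percentages`) covers chimera contribution counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DotRecord",
    "ScoreBins",
    "MarkerCrossTab",
    "assign_score",
    "score_records",
    "marker_crosstab",
    "chimerism_percentages",
]


@dataclass(frozen=True)
class DotRecord:
    """One cell's dot count, cluster flag and marker status."""

    cell_id: str
    dot_count: int
    has_big_cluster: bool = False
    marker_positive: bool = False
    section_id: str | None = None
    embryo_id: str | None = None

    def __post_init__(self) -> None:
        if self.dot_count < 0:
            raise ValueError(f"cell {self.cell_id!r}: negative dot count")


@dataclass(frozen=True)
class ScoreBins:
    """Mapping from dot counts (and the cluster flag) to an ordinal score.

    ``edges`` are the lower bounds of the score-1..score-k count bins; counts
    below the first edge score 0. With the default ``edges=(1, 4, 10)``:
    0 dots -> 0, 1-3 -> 1, 4-9 -> 2, >=10 -> 3. A big cluster always maps to
    the top score: 4 on the default 0-4 scale, the last count bin (3) when
    ``cluster_is_own_score`` is False.
    """

    edges: tuple[int, ...] = (1, 4, 10)
    cluster_is_own_score: bool = True

    def __post_init__(self) -> None:
        if not self.edges or any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing and nonempty")
        if self.edges[0] < 1:
            raise ValueError("the first edge must be >= 1 (0 dots always scores 0)")

    @property
    def max_score(self) -> int:
        return len(self.edges) + (1 if self.cluster_is_own_score else 0)

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(range(self.max_score + 1))

    def score(self, dot_count: int, has_big_cluster: bool = False) -> int:
        if dot_count < 0:
            raise ValueError("negative dot count")
        if has_big_cluster:
            return self.max_score
        return int(np.searchsorted(self.edges, dot_count, side="right"))


@dataclass
class MarkerCrossTab:
    """Marker-status x score counts with the derived summary percentages.

    Percentages are computed from the same counts they summarize:
    ``pct_marker_positive`` over all cells, ``pct_low_in_positive`` within the
    marker-positive class and ``pct_high_in_negative`` within the negatives.
    A percentage over an empty class is None and flagged in ``undefined``.
    """

    counts: pd.DataFrame  # index: marker_positive / marker_negative; columns: scores
    n_total: int
    pct_marker_positive: float
    pct_low_in_positive: float | None
    pct_high_in_negative: float | None
    low_scores: tuple[int, ...]
    high_scores: tuple[int, ...]
    undefined: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 0) -> dict[str, float | None]:
        """Reported percentages at the configured rounding (default: integer)."""
        def rnd(v):
            if v is None:
                return None
            r = round(v, ndigits)
            return r if ndigits > 0 else int(r)

        return {
            "pct_marker_positive": rnd(self.pct_marker_positive),
            "pct_low_in_positive": rnd(self.pct_low_in_positive),
            "pct_high_in_negative": rnd(self.pct_high_in_negative),
        }


def assign_score(record: DotRecord, bins: ScoreBins | None = None) -> int:
    """Ordinal score of one cell under the given (default 0-4) bins."""
    bins = bins or ScoreBins()
    return bins.score(record.dot_count, record.has_big_cluster)


def score_records(
    records: Iterable[DotRecord], bins: ScoreBins | None = None
) -> pd.DataFrame:
    """Tidy table of records with their assigned scores."""
    bins = bins or ScoreBins()
    rows = [
        {
            "cell_id": r.cell_id,
            "dot_count": r.dot_count,
            "has_big_cluster": r.has_big_cluster,
            "marker_positive": r.marker_positive,
            "score": bins.score(r.dot_count, r.has_big_cluster),
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no dot records")
    return pd.DataFrame(rows)


def marker_crosstab(
    records: Sequence[DotRecord],
    bins: ScoreBins | None = None,
    low: Iterable[int] = (0, 1),
    high: Iterable[int] = (3, 4),
) -> MarkerCrossTab:
    """Cross-tabulate marker status against score and derive the summary rates."""
    bins = bins or ScoreBins()
    table = score_records(records, bins)
    low = tuple(sorted(set(low)))
    high = tuple(sorted(set(high)))
    counts = pd.DataFrame(
        0, index=["marker_positive", "marker_negative"], columns=list(bins.scores)
    )
    for _, row in table.iterrows():
        key = "marker_positive" if row["marker_positive"] else "marker_negative"
        counts.loc[key, row["score"]] += 1
    n_total = int(counts.to_numpy().sum())
    n_pos = int(counts.loc["marker_positive"].sum())
    n_neg = int(counts.loc["marker_negative"].sum())
    undefined: list[str] = []
    pct_pos = 100.0 * n_pos / n_total
    if n_pos:
        low_cols = [s for s in low if s in counts.columns]
        pct_low = 100.0 * counts.loc["marker_positive", low_cols].sum() / n_pos
    else:
        pct_low = None
        undefined.append("pct_low_in_positive")
    if n_neg:
        high_cols = [s for s in high if s in counts.columns]
        pct_high = 100.0 * counts.loc["marker_negative", high_cols].sum() / n_neg
    else:
        pct_high = None
        undefined.append("pct_high_in_negative")
    return MarkerCrossTab(
        counts=counts,
        n_total=n_total,
        pct_marker_positive=float(pct_pos),
        pct_low_in_positive=None if pct_low is None else float(pct_low),
        pct_high_in_negative=None if pct_high is None else float(pct_high),
        low_scores=low,
        high_scores=high,
        undefined=undefined,
    )


def chimerism_percentages(
    records: Iterable[tuple[str, bool, str]],
    compartments: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-compartment percentage of reporter-positive cells.

    ``records`` are ``(cell_id, reporter_positive, compartment)`` triples.
    When ``compartments`` is given, a record with an unknown label is an
    error; otherwise labels are taken from the data. Totals are reported
    alongside the percentages.
    """
    rows = list(records)
    if not rows:
        raise ValueError("no records")
    known = set(compartments) if compartments is not None else None
    tally: dict[str, list[int]] = {}
    for cell_id, positive, comp in rows:
        if known is not None and comp not in known:
            raise ValueError(f"unknown compartment label {comp!r} (cell {cell_id!r})")
        n = tally.setdefault(comp, [0, 0])
        n[0] += 1
        n[1] += int(bool(positive))
    out = pd.DataFrame(
        [
            {"compartment": c, "n_total": t, "n_positive": p, "pct_positive": 100.0 * p / t}
            for c, (t, p) in sorted(tally.items())
        ]
    ).set_index("compartment")
    return out
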