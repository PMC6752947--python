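"""Single-cell and bulk qPCR expression pipeline.

The pipeline converts raw cycle-threshold (Ct) values from a microfluidic
qPCR run into relative expression, normalizes to housekeeping genes, filters
low-quality and contaminating cells, and measures pairwise gene co-expression
with Spearman correlations under pairwise-complete missing-data handling.

Stages, in order:

1. ``compute_lod`` — the limit of detection (LOD), in cycles, is the ceiling
   of the mean per-gene maximum Ct over non-failed wells.
2. ``ct_to_expression`` — relative expression on a log2 scale,
   ``Log2ex = max(0, LOD - Ct)``; a well is *detected* iff Ct < LOD.
3. ``normalize_to_controls`` — per-cell housekeeping mean subtracted, then a
   global offset (the mean of the per-cell means) added back so values stay
   nonnegative on average.
4. ``filter_cells`` — keep a cell iff it detects no exclusion marker, at
   least ``min_controls`` housekeeping genes, and at least ``min_interest``
   readout genes.
5. ``spearman_correlogram`` — mid-rank Spearman rho and two-sided p per gene
   pair over pairwise-complete observations, with undetected values treated
   as missing.

Each stage is exposed both as a plain function and as a scikit-learn style
estimator (``ExpressionConverter``, ``HousekeepingNormalizer``,
``CellQualityFilter``, ``SpearmanCorrelogram``) whose fitted attributes carry
the recorded parameters (LOD, offset, filter report, rho/p matrices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import GenePanel, default_panel

__all__ = [
    "CtMatrix",
    "Lod",
    "ExpressionMatrix",
    "FilterReport",
    "CorrelationResult",
    "PrimerCalibration",
    "compute_lod",
    "ct_to_expression",
    "normalize_to_controls",
    "filter_cells",
    "spearman_correlogram",
    "heatmap_order",
    "complete_linkage",
    "primer_efficiency",
    "bulk_relative_expression",
    "ExpressionConverter",
    "HousekeepingNormalizer",
    "CellQualityFilter",
    "SpearmanCorrelogram",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CtMatrix:
    """Raw genes x cells Ct matrix with a fail mask for no-amplification wells.

    ``values`` holds Ct in PCR cycles (NaN at failed wells); ``fail_mask`` is
    True where the instrument called no amplification.
    """

    values: pd.DataFrame
    fail_mask: pd.DataFrame
    panel: GenePanel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.fail_mask.shape:
            raise ValueError("values and fail_mask shapes differ")
        if not self.values.index.equals(self.fail_mask.index) or not self.values.columns.equals(
            self.fail_mask.columns
        ):
            raise ValueError("values and fail_mask must share gene/cell labels")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene names")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        ok = self.values.to_numpy()[~self.fail_mask.to_numpy()]
        if ok.size and (not np.all(np.isfinite(ok)) or np.any(ok <= 0)):
            raise ValueError("non-failed Ct values must be finite and > 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Lod:
    """Limit of detection: ceiling of the mean per-gene maximum Ct."""

    value: int
    per_gene_max: pd.Series

    def __post_init__(self) -> None:
        expected = int(math.ceil(float(self.per_gene_max.mean())))
        if self.value != expected:
            raise ValueError(
                f"LOD {self.value} inconsistent with per-gene maxima (expect {expected})"
            )


@dataclass
class ExpressionMatrix:
    """Relative expression (Log2ex) with a detection mask.

    Unnormalized values are nonnegative; after normalization the recorded
    ``offset`` is the mean per-cell housekeeping level that was added back.
    ``detected_mask`` stays attached across normalization and decides whether
    a value enters downstream steps as 0 (clustering) or missing (correlation).
    """

    values: pd.DataFrame
    detected_mask: pd.DataFrame
    lod: Lod
    panel: GenePanel | None = None
    normalized: bool = False
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.detected_mask.shape:
            raise ValueError("values and detected_mask shapes differ")
        if self.normalized != (self.offset is not None):
            raise ValueError("offset must be present iff normalized")
        if not self.normalized:
            vals = self.values.to_numpy()
            if np.any(vals < 0):
                raise ValueError("unnormalized expression must be nonnegative")
            if np.any(vals[~self.detected_mask.to_numpy()] != 0):
                raise ValueError("undetected wells must be 0 before normalization")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.loc[:, list(cells)],
            detected_mask=self.detected_mask.loc[:, list(cells)],
        )

    def masked(self, *, missing: bool) -> pd.DataFrame:
        """Values with undetected wells as NaN (``missing=True``) or 0."""
        if missing:
            return self.values.where(self.detected_mask)
        return self.values.where(self.detected_mask, 0.0)


@dataclass
class FilterReport:
    """Per-cell retain/discard verdicts with the failed criteria spelled out."""

    verdicts: pd.Series            # cell id -> "retained" | "discarded"
    reasons: dict[str, list[str]]  # cell id -> list of failed criteria
    n_input: int
    n_retained: int

    @property
    def retained_cells(self) -> list[str]:
        return [c for c, v in self.verdicts.items() if v == "retained"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "verdict": self.verdicts,
                "reasons": pd.Series(
                    {c: ";".join(r) for c, r in self.reasons.items()}
                ).reindex(self.verdicts.index, fill_value=""),
            }
        ).rename_axis("cell_id")


@dataclass
class CorrelationResult:
    """Genes x genes Spearman rho, two-sided p and pair counts.

    Entries with fewer than ``min_pairs`` complete observations, or where a
    variable is constant over the complete pairs, are NaN — never silently 0.
    """

    rho: pd.DataFrame
    pval: pd.DataFrame
    n_pairs: pd.DataFrame


@dataclass(frozen=True)
class PrimerCalibration:
    """Primer amplification efficiency from a dilution-series regression.

    ``efficiency = 10 ** (-1 / slope)`` where ``slope`` is the slope of Ct
    against log10(dilution); a perfect doubling assay has slope -3.32, E = 2.
    """

    slope: float
    efficiency: float

    @classmethod
    def from_slope(cls, slope: float) -> "PrimerCalibration":
        return cls(slope=float(slope), efficiency=primer_efficiency(slope))

    @classmethod
    def from_dilution_series(
        cls, log10_dilution: Sequence[float], ct: Sequence[float]
    ) -> "PrimerCalibration":
        res = stats.linregress(np.asarray(log10_dilution, float), np.asarray(ct, float))
        return cls.from_slope(res.slope)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_lod(ct: CtMatrix, gene_subset: Iterable[str] | None = None) -> Lod:
    """Limit of detection in cycles from per-gene maximum non-failed Ct."""
    genes = list(gene_subset) if gene_subset is not None else list(ct.genes)
    if not genes or ct.n_cells == 0:
        raise ValueError("cannot compute LOD on an empty matrix")
    unknown = [g for g in genes if g not in ct.genes]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    vals = ct.values.loc[genes].where(~ct.fail_mask.loc[genes])
    all_failed = vals.isna().all(axis=1)
    if all_failed.any():
        bad = list(vals.index[all_failed])
        raise ValueError(f"gene(s) with only failed wells: {bad}")
    per_gene_max = vals.max(axis=1)
    return Lod(value=int(math.ceil(float(per_gene_max.mean()))), per_gene_max=per_gene_max)


def ct_to_expression(ct: CtMatrix, lod: Lod) -> ExpressionMatrix:
    """Convert Ct to Log2ex = max(0, LOD - Ct); failed wells become 0, undetected."""
    raw = lod.value - ct.values
    detected = (raw > 0) & ~ct.fail_mask
    values = raw.where(detected, 0.0).astype(float)
    return ExpressionMatrix(
        values=values, detected_mask=detected, lod=lod, panel=ct.panel
    )


def normalize_to_controls(
    expr: ExpressionMatrix, normalizers: Iterable[str] | None = None
) -> ExpressionMatrix:
    """Subtract each cell's housekeeping mean, then add the global offset.

    The housekeeping mean ``h_c`` of a cell is the mean of its normalizer-gene
    Log2ex values (zeros included). The offset is the mean of all ``h_c``; the
    shift ``-h_c + offset`` is applied to every value of the cell so that,
    after normalization, every cell's normalizer mean equals the offset.
    """
    if expr.normalized:
        raise ValueError("expression matrix is already normalized")
    if normalizers is None:
        if expr.panel is None:
            raise ValueError("no normalizer genes given and matrix has no panel")
        normalizers = expr.panel.normalizer_genes
    norm = [g for g in normalizers]
    missing = [g for g in norm if g not in expr.genes]
    if missing:
        raise KeyError(f"normalizer genes not in matrix: {missing}")
    if not norm:
        raise ValueError("empty normalizer set")
    h = expr.values.loc[norm].mean(axis=0)  # per-cell housekeeping mean
    if h.isna().any():
        raise ValueError(f"cells without usable normalizer values: {list(h.index[h.isna()])}")
    offset = float(h.mean())
    values = expr.values.sub(h, axis=1).add(offset)
    return replace(expr, values=values, normalized=True, offset=offset)


def filter_cells(
    expr: ExpressionMatrix,
    panel: GenePanel | None = None,
    min_controls: int = 4,
    min_interest: int = 2,
    exclusion: Iterable[str] | None = None,
) -> FilterReport:
    """Retain cells with clean marker profile and sufficient detected genes.

    A cell passes iff it detects no exclusion marker, at least ``min_controls``
    of the control genes and at least ``min_interest`` of the interest genes.
    """
    panel = panel or expr.panel
    if panel is None:
        raise ValueError("a gene panel is required for filtering")
    controls = [g for g in panel.control_genes if g in expr.genes]
    interest = [g for g in panel.interest_genes if g in expr.genes]
    excl = list(exclusion) if exclusion is not None else [
        g for g in panel.exclusion_genes if g in expr.genes
    ]
    if min_controls > len(controls):
        raise ValueError(
            f"min_controls={min_controls} exceeds the {len(controls)} control genes present"
        )
    det = expr.detected_mask
    n_ctrl = det.loc[controls].sum(axis=0) if controls else pd.Series(0, index=expr.cell_ids)
    n_int = det.loc[interest].sum(axis=0) if interest else pd.Series(0, index=expr.cell_ids)
    any_excl = (
        det.loc[[g for g in excl if g in expr.genes]].any(axis=0)
        if excl
        else pd.Series(False, index=expr.cell_ids)
    )

    verdicts, reasons = {}, {}
    for cell in expr.cell_ids:
        fails: list[str] = []
        if bool(any_excl[cell]):
            fails.append("exclusion_marker_detected")
        if int(n_ctrl[cell]) < min_controls:
            fails.append(f"controls_detected<{min_controls}")
        if int(n_int[cell]) < min_interest:
            fails.append(f"interest_detected<{min_interest}")
        verdicts[cell] = "discarded" if fails else "retained"
        if fails:
            reasons[cell] = fails
    verdict_series = pd.Series(verdicts).reindex(expr.cell_ids)
    return FilterReport(
        verdicts=verdict_series,
        reasons=reasons,
        n_input=len(expr.cell_ids),
        n_retained=int((verdict_series == "retained").sum()),
    )


def spearman_correlogram(
    expr: ExpressionMatrix | pd.DataFrame,
    zero_as_missing: bool = True,
    min_pairs: int = 3,
    genes: Iterable[str] | None = None,
) -> CorrelationResult:
    """Pairwise-complete Spearman correlation matrix with two-sided p-values.

    Undetected (null) values are converted to missing when ``zero_as_missing``
    is set, so each gene pair is correlated over the cells where both genes
    were detected. Rho is the Pearson correlation of mid-ranks; p uses the
    t-approximation with ``df = n_pairs - 2``. Pairs with fewer than
    ``min_pairs`` complete observations, or with a constant variable, are NaN.
    """
    if isinstance(expr, ExpressionMatrix):
        data = expr.masked(missing=zero_as_missing)
    else:
        data = expr.astype(float)
        if zero_as_missing:
            data = data.where(data != 0)
    if genes is not None:
        data = data.loc[list(genes)]
    if data.shape[0] < 2:
        raise ValueError("need at least two genes to correlate")
    gene_list = list(data.index)
    n = len(gene_list)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    npairs = np.zeros((n, n), dtype=int)
    arr = data.to_numpy()
    for i in range(n):
        for j in range(i, n):
            both = ~np.isnan(arr[i]) & ~np.isnan(arr[j])
            m = int(both.sum())
            npairs[i, j] = npairs[j, i] = m
            if m < min_pairs:
                continue
            x, y = arr[i, both], arr[j, both]
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            if i == j:
                rho[i, j], pval[i, j] = 1.0, 0.0
                continue
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    idx = pd.Index(gene_list, name="gene")
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=gene_list),
        pval=pd.DataFrame(pval, index=idx, columns=gene_list),
        n_pairs=pd.DataFrame(npairs, index=idx, columns=gene_list),
    )


# ---------------------------------------------------------------------------
# hierarchical ordering for heatmaps
# ---------------------------------------------------------------------------

def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage over a square distance matrix.

    Returns a scipy-compatible linkage matrix. Equal-height merge candidates
    are broken deterministically toward the pair whose clusters contain the
    lowest original leaf indices (lexicographically).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    # cluster id -> (member leaf set, min-leaf key)
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    active = list(range(n))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (min(a, b), max(a, b))
                h = d[key]
                tie_key = tuple(sorted((min(members[a]), min(members[b]))))
                cand = (h, tie_key, key)
                if best is None or cand < best:
                    best = cand
        h, _, (a, b) = best
        merged = members[a] | members[b]
        members[next_id] = merged
        Z[step] = (a, b, h, len(merged))
        active = [c for c in active if c not in (a, b)]
        for c in active:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            d[(min(next_id, c), max(next_id, c))] = max(d[ka], d[kb])
        active.append(next_id)
        next_id += 1
    return Z


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order; the child containing the lowest leaf goes left."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(Z.shape[0]):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        left, right = members.pop(a), members.pop(b)
        if min(right) < min(left):
            left, right = right, left
        members[n + step] = left + right
    (order,) = members.values()
    return order


def heatmap_order(
    expr: ExpressionMatrix | pd.DataFrame,
) -> tuple[list[str], list[str], np.ndarray | None, np.ndarray | None]:
    """Row (gene) and column (cell) orders for a clustered heatmap.

    Undetected entries enter the clustering as 0. Rows and columns are
    clustered independently with Euclidean distance and complete linkage.
    Returns ``(row_order, col_order, row_linkage, col_linkage)``; linkages are
    None for singleton axes.
    """
    data = expr.masked(missing=False) if isinstance(expr, ExpressionMatrix) else expr
    arr = data.to_numpy(dtype=float)

    def axis_order(mat: np.ndarray, labels: pd.Index):
        k = mat.shape[0]
        if k <= 1:
            return list(labels), None
        dm = np.sqrt(((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2))
        Z = complete_linkage(dm)
        return [labels[i] for i in _leaf_order(Z, k)], Z

    row_order, row_Z = axis_order(arr, data.index)
    col_order, col_Z = axis_order(arr.T, data.columns)
    return row_order, col_order, row_Z, col_Z


# ---------------------------------------------------------------------------
# bulk qPCR helpers
# ---------------------------------------------------------------------------

def primer_efficiency(slope: float) -> float:
    """Amplification efficiency E = 10**(-1/slope) from a dilution-series slope."""
    slope = float(slope)
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return 10.0 ** (-1.0 / slope)


def bulk_relative_expression(
    ct_target: float, ct_reference: float, fail_sentinel: float = 999.0
) -> float:
    """Linear expression of a target relative to a reference gene, 2**(dCt)."""
    ct_target, ct_reference = float(ct_target), float(ct_reference)
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not math.isfinite(v) or v >= fail_sentinel:
            raise ValueError(f"{name} is a failed-well or non-finite value: {v}")
    return 2.0 ** (ct_reference - ct_target)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

class ExpressionConverter(BaseEstimator, TransformerMixin):
    """Fit the LOD on a Ct matrix; transform Ct to relative expression.

    Parameters
    ----------
    lod : int, optional
        Fixed LOD in cycles; when None the LOD is computed at fit time.
    gene_subset : iterable of str, optional
        Genes entering the LOD mean (default: all genes in the matrix).

    Attributes
    ----------
    lod_ : Lod
        The limit of detection used by :meth:`transform`.
    """

    def __init__(self, lod: int | None = None, gene_subset: Iterable[str] | None = None):
        self.lod = lod
        self.gene_subset = gene_subset

    def fit(self, X: CtMatrix, y=None) -> "ExpressionConverter":
        if self.lod is not None:
            computed = compute_lod(X, self.gene_subset)
            self.lod_ = Lod.__new__(Lod)  # fixed LOD keeps the observed maxima
            object.__setattr__(self.lod_, "value", int(self.lod))
            object.__setattr__(self.lod_, "per_gene_max", computed.per_gene_max)
        else:
            self.lod_ = compute_lod(X, self.gene_subset)
        return self

    def transform(self, X: CtMatrix) -> ExpressionMatrix:
        return ct_to_expression(X, self.lod_)


class HousekeepingNormalizer(BaseEstimator, TransformerMixin):
    """Fit the per-cell housekeeping means and global offset; transform applies them."""

    def __init__(self, normalizers: Iterable[str] | None = None):
        self.normalizers = normalizers

    def fit(self, X: ExpressionMatrix, y=None) -> "HousekeepingNormalizer":
        out = normalize_to_controls(X, self.normalizers)
        self.offset_ = out.offset
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        return normalize_to_controls(X, self.normalizers)

    def fit_transform(self, X: ExpressionMatrix, y=None) -> ExpressionMatrix:
        out = normalize_to_controls(X, self.normalizers)
        self.offset_ = out.offset
        return out


class CellQualityFilter(BaseEstimator, TransformerMixin):
    """Fit records the filter report; transform drops discarded cells."""

    def __init__(
        self,
        min_controls: int = 4,
        min_interest: int = 2,
        exclusion: Iterable[str] | None = None,
    ):
        self.min_controls = min_controls
        self.min_interest = min_interest
        self.exclusion = exclusion

    def fit(self, X: ExpressionMatrix, y=None) -> "CellQualityFilter":
        self.report_ = filter_cells(
            X,
            min_controls=self.min_controls,
            min_interest=self.min_interest,
            exclusion=self.exclusion,
        )
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        report = filter_cells(
            X,
            min_controls=self.min_controls,
            min_interest=self.min_interest,
            exclusion=self.exclusion,
        )
        return X.subset_cells(report.retained_cells)


class SpearmanCorrelogram(BaseEstimator):
    """Fit computes the pairwise-complete Spearman correlation matrices.

    Attributes
    ----------
    result_ : CorrelationResult
    rho_, pval_, n_pairs_ : pandas.DataFrame
    """

    def __init__(
        self,
        zero_as_missing: bool = True,
        min_pairs: int = 3,
        genes: Iterable[str] | None = None,
    ):
        self.zero_as_missing = zero_as_missing
        self.min_pairs = min_pairs
        self.genes = genes

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None) -> "SpearmanCorrelogram":
        self.result_ = spearman_correlogram(
            X, zero_as_missing=self.zero_as_missing, min_pairs=self.min_pairs, genes=self.genes
        )
        self.rho_ = self.result_.rho
        self.pval_ = self.result_.pval
        self.n_pairs_ = self.result_.n_pairs
        return self
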