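"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Four generators emulate the four kinds of raw data the analyses consume:

- :func:`simulate_ct_matrix` — a BioMark-like genes x cells Ct matrix. Latent
  log2 expression is drawn from a block-correlated multivariate normal: the
  upstream progenitor genes (Isl1, Met, Pax7, Myf5) form a positively
  correlated, nearly always detected block; the downstream MRFs (Myod, Myog,
  Mrf4) form a sparsely detected block; five housekeeping genes are high-mean
  and stable. Ct = LOD_true - latent; a well with latent <= 0 is below the
  detection limit and is recorded as a failed (no-amplification, sentinel)
  well, so dropout is pure LOD censoring. A fraction of cells are neurogenic
  contaminants (express the exclusion markers) and a fraction are low-quality
  (fail >= 2 control genes).
- :func:`simulate_tracks` — biased persistent random walks under a "control"
  vs "inhibitor" drift, emulating posterior (toward-stomach) migration of
  progenitors in explants and its slowdown under MET inhibition.
- :func:`simulate_dot_records` — per-cell transcript dot counts whose
  negative-binomial mean depends on differentiation-marker status
  (undifferentiated cells carry many dots, differentiated ones few).
- :func:`simulate_section_image` — disks of constant intensity over a noisy
  background, with the ground-truth foreground mask, for threshold testing.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    DOWNSTREAM_BLOCK,
    GenePanel,
    UPSTREAM_BLOCK,
    default_panel,
)
from .qpcr import CtMatrix
from .rnascope import DotRecord
from .tracks import Track

__all__ = [
    "QpcrSimParams",
    "TrackSimParams",
    "DotSimParams",
    "ImageSimParams",
    "simulate_ct_matrix",
    "simulate_tracks",
    "simulate_dot_records",
    "simulate_section_image",
]


# ---------------------------------------------------------------------------
# single-cell qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimParams:
    """Study-default conditions: 66 collected cells, ~23 clean, LOD 21.

    Latent means/sds are on the Log2ex scale (latent = LOD_true - Ct).
    ``block_rho_upstream`` correlates the progenitor block, and
    ``block_rho_downstream`` the MRF block; cross-block latent correlation
    is zero (the planted null). ``fail_cycles`` is the sentinel recorded for
    no-amplification wells.
    """

    n_cells: int = 66
    lod_true: float = 21.0
    control_mean: float = 6.0
    control_sd: float = 2.5
    upstream_mean: float = 5.0
    upstream_sd: float = 2.5
    downstream_mean: float = -2.0
    downstream_sd: float = 2.5
    block_rho_upstream: float = 0.75
    block_rho_downstream: float = 0.5
    exclusion_mean_contaminant: float = 4.0
    exclusion_sd: float = 2.5
    fraction_contaminant: float = 0.30
    fraction_low_quality: float = 0.35
    n_controls_failed_low_quality: int = 3
    fail_cycles: float = 999.0
    panel: GenePanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        for name in ("fraction_contaminant", "fraction_low_quality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_contaminant + self.fraction_low_quality > 1.0:
            raise ValueError("contaminant + low-quality fractions exceed 1")
        for name in ("block_rho_upstream", "block_rho_downstream"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


def _equicorrelated(k: int, rho: float) -> np.ndarray:
    c = np.full((k, k), rho)
    np.fill_diagonal(c, 1.0)
    # equicorrelation is PSD iff rho >= -1/(k-1); validated here
    if k > 1 and rho < -1.0 / (k - 1):
        raise ValueError("correlation matrix not positive semidefinite")
    return c


def latent_correlation_matrix(params: QpcrSimParams) -> tuple[list[str], np.ndarray]:
    """Genes and the planted latent correlation matrix (block-diagonal)."""
    panel = params.panel
    genes = list(panel.genes)
    k = len(genes)
    corr = np.eye(k)

    def plant(block: tuple[str, ...], rho: float) -> None:
        idx = [genes.index(g) for g in block if g in genes]
        sub = _equicorrelated(len(idx), rho)
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                corr[ia, ib] = sub[a, b]

    plant(tuple(g for g in UPSTREAM_BLOCK), params.block_rho_upstream)
    plant(tuple(g for g in DOWNSTREAM_BLOCK), params.block_rho_downstream)
    return genes, corr


def simulate_ct_matrix(
    params: QpcrSimParams | None = None, seed: int = 0
) -> tuple[CtMatrix, dict]:
    """Generate a Ct matrix plus ground truth (cell classes, latents, blocks)."""
    params = params or QpcrSimParams()
    panel = params.panel
    rng = np.random.default_rng(seed)
    genes, corr = latent_correlation_matrix(params)
    k = len(genes)
    n = params.n_cells

    means = np.zeros(k)
    sds = np.ones(k)
    for i, g in enumerate(genes):
        role = panel.roles[g]
        if role == "control":
            means[i], sds[i] = params.control_mean, params.control_sd
        elif role == "exclusion":
            # clean cells: far below detection; contaminants overridden below
            means[i], sds[i] = -8.0, 1.0
        elif g in DOWNSTREAM_BLOCK:
            means[i], sds[i] = params.downstream_mean, params.downstream_sd
        else:
            means[i], sds[i] = params.upstream_mean, params.upstream_sd

    cov = corr * np.outer(sds, sds)
    latent = rng.multivariate_normal(means, cov, size=n, method="cholesky").T  # genes x cells

    # cell classes: contaminant, low-quality, clean
    n_cont = int(round(params.fraction_contaminant * n))
    n_low = int(round(params.fraction_low_quality * n))
    classes = np.array(
        ["contaminant"] * n_cont + ["low_quality"] * n_low + ["clean"] * (n - n_cont - n_low)
    )
    rng.shuffle(classes)

    excl_idx = [genes.index(g) for g in panel.exclusion_genes if g in genes]
    ctrl_idx = [genes.index(g) for g in panel.control_genes if g in genes]
    for c in np.nonzero(classes == "contaminant")[0]:
        for gi in excl_idx:
            latent[gi, c] = params.exclusion_mean_contaminant + params.exclusion_sd * rng.standard_normal()
    for c in np.nonzero(classes == "low_quality")[0]:
        failed = rng.choice(ctrl_idx, size=params.n_controls_failed_low_quality, replace=False)
        for gi in failed:
            latent[gi, c] = -3.0 + rng.standard_normal()

    detected_truth = latent > 0
    ct = params.lod_true - latent
    ct = np.clip(ct, 1.0, None)  # Ct must stay positive
    fail = ~detected_truth  # below the detection limit -> no amplification call
    values = np.where(fail, np.nan, ct)

    cell_ids = [f"cell{c + 1:03d}" for c in range(n)]
    idx = pd.Index(genes, name="gene")
    cols = pd.Index(cell_ids, name="cell_id")
    matrix = CtMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        fail_mask=pd.DataFrame(fail, index=idx, columns=cols),
        panel=panel,
        metadata={"simulated": True, "seed": seed, "fail_sentinel": params.fail_cycles},
    )
    truth = {
        "cell_class": pd.Series(classes, index=cols),
        "latent": pd.DataFrame(latent, index=idx, columns=cols),
        "detected": pd.DataFrame(detected_truth, index=idx, columns=cols),
        "upstream_block": [g for g in UPSTREAM_BLOCK if g in genes],
        "downstream_block": [g for g in DOWNSTREAM_BLOCK if g in genes],
        "latent_correlation": pd.DataFrame(corr, index=idx, columns=genes),
        "lod_true": params.lod_true,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# migration tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSimParams:
    """Biased persistent random walk conditions.

    Defaults follow the explant imaging setup: a frame every 15 minutes over
    14 hours (57 frames), 30 tracks per condition, posterior (+x) drift of
    0.3 μm/min in controls vs 0.1 μm/min under MET inhibition, an intrinsic
    motility of 0.15 μm/min with heading persistence 0.6 per frame, and 1 μm
    positional jitter.
    """

    n_tracks: int = 30
    n_frames: int = 57
    frame_interval_min: float = 15.0
    drift_um_per_min: dict[str, float] = field(
        default_factory=lambda: {"control": 0.3, "inhibitor": 0.1}
    )
    motility_um_per_min: float = 0.15
    persistence: float = 0.6
    noise_sd_um: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.n_frames < 2 or self.n_tracks < 1 or self.frame_interval_min <= 0:
            raise ValueError("invalid track simulation sizes")
        if self.noise_sd_um < 0 or self.motility_um_per_min < 0:
            raise ValueError("noise and motility must be nonnegative")


def simulate_tracks(
    params: TrackSimParams | None = None, seed: int = 0
) -> dict[str, list[Track]]:
    """Tracks per condition. Heading evolves by a wrapped-normal perturbation
    whose spread shrinks with persistence (sd = pi * (1 - persistence));
    each step adds drift along +x, the motility step along the heading, and
    isotropic Gaussian jitter."""
    params = params or TrackSimParams()
    rng = np.random.default_rng(seed)
    dt = params.frame_interval_min
    sigma_theta = np.pi * (1.0 - params.persistence)
    out: dict[str, list[Track]] = {}
    for cond, drift in params.drift_um_per_min.items():
        tracks = []
        for t in range(params.n_tracks):
            theta = rng.uniform(-np.pi, np.pi)
            pos = np.zeros((params.n_frames, 2))
            pos[0] = rng.uniform(0, 100, size=2)
            for f in range(1, params.n_frames):
                theta = np.mod(
                    theta + sigma_theta * rng.standard_normal() + np.pi, 2 * np.pi
                ) - np.pi
                step = (
                    np.array([drift * dt, 0.0])
                    + params.motility_um_per_min * dt * np.array([np.cos(theta), np.sin(theta)])
                    + params.noise_sd_um * rng.standard_normal(2)
                )
                pos[f] = pos[f - 1] + step
            tracks.append(
                Track(
                    track_id=f"{cond}_{t + 1:02d}",
                    frames=np.arange(params.n_frames),
                    x=pos[:, 0],
                    y=pos[:, 1],
                    frame_interval_min=dt,
                )
            )
        out[cond] = tracks
    return out


def tracks_to_frame(tracks_by_condition: dict[str, list[Track]]) -> pd.DataFrame:
    """Tidy (condition, track_id, frame, x, y) table for CSV export."""
    rows = []
    for cond, tracks in tracks_by_condition.items():
        for t in tracks:
            for f, x, y in zip(t.frames, t.x, t.y):
                rows.append(
                    {"condition": cond, "track_id": t.track_id, "frame": int(f), "x": x, "y": y}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNAscope dots
# ---------------------------------------------------------------------------

@dataclass
class DotSimParams:
    """Dot-count conditions mirroring the in-situ quantification: 368 cells,
    34% differentiation-marker positive; marker-negative (undifferentiated)
    cells carry many transcript dots (NB mean 12), marker-positive
    (differentiating) cells few (NB mean 2)."""

    n_cells: int = 368
    p_marker_positive: float = 0.34
    nb_mean_positive: float = 2.0
    nb_mean_negative: float = 12.0
    nb_dispersion: float = 2.0  # NB size parameter; variance = m + m^2/size
    p_cluster_positive: float = 0.02
    p_cluster_negative: float = 0.20

    def __post_init__(self) -> None:
        for name in ("p_marker_positive", "p_cluster_positive", "p_cluster_negative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_mean_positive <= 0 or self.nb_mean_negative <= 0 or self.nb_dispersion <= 0:
            raise ValueError("NB means and dispersion must be positive")


def simulate_dot_records(
    params: DotSimParams | None = None, seed: int = 0
) -> tuple[list[DotRecord], pd.DataFrame]:
    """Per-cell dot records plus the ground-truth table."""
    params = params or DotSimParams()
    rng = np.random.default_rng(seed)
    marker = rng.random(params.n_cells) < params.p_marker_positive
    size = params.nb_dispersion
    records, rows = [], []
    for i in range(params.n_cells):
        mean = params.nb_mean_positive if marker[i] else params.nb_mean_negative
        p = size / (size + mean)
        dots = int(rng.negative_binomial(size, p))
        p_cluster = params.p_cluster_positive if marker[i] else params.p_cluster_negative
        cluster = bool(rng.random() < p_cluster)
        rec = DotRecord(
            cell_id=f"cell{i + 1:04d}",
            dot_count=dots,
            has_big_cluster=cluster,
            marker_positive=bool(marker[i]),
        )
        records.append(rec)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "dots": dots,
                "cluster": int(cluster),
                "marker": int(marker[i]),
                "nb_mean": mean,
            }
        )
    return records, pd.DataFrame(rows).set_index("cell_id")


# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Blobs-over-background conditions for threshold testing (8-bit)."""

    shape: tuple[int, int] = (256, 256)
    n_blobs: int = 12
    blob_radius_px: float = 10.0
    blob_intensity: int = 180
    background_level: int = 30
    noise_sd: float = 10.0
    seed_margin_px: int = 12

    def __post_init__(self) -> None:
        if self.blob_intensity <= self.background_level:
            raise ValueError("blob intensity must exceed the background level")
        if self.noise_sd < 0 or self.n_blobs < 0 or self.blob_radius_px <= 0:
            raise ValueError("invalid image simulation parameters")


def simulate_section_image(
    params: ImageSimParams | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy 8-bit image of uniform disks plus its ground-truth foreground mask."""
    params = params or ImageSimParams()
    rng = np.random.default_rng(seed)
    h, w = params.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    m = params.seed_margin_px
    for _ in range(params.n_blobs):
        cy = rng.uniform(m, h - m)
        cx = rng.uniform(m, w - m)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= params.blob_radius_px**2
    image = np.where(mask, float(params.blob_intensity), float(params.background_level))
    image = image + params.noise_sd * rng.standard_normal((h, w))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, mask
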