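"""ImageJ-style automatic thresholds and masked area measurements.

Two histogram thresholding methods are provided, matching the Fiji/ImageJ
menu entries used for section quantification:

``"default"``
    The legacy ImageJ iterative intermeans ("IJ Default") variant: the
    extreme histogram bins are zeroed first (so saturated/erased pixels do
    not drag the intermeans), then the threshold is iterated to the fixed
    point ``T = round((mean below T + mean above T) / 2)``.
``"isodata"``
    The classic Ridler-Calvard iterative intermeans without the extreme-bin
    special case.
``"huang"``
    Huang & Wang's fuzzy-entropy minimizer: for each candidate T, pixels get
    a fuzzy membership ``mu(g) = 1 / (1 + |g - m(g,T)| / C)`` to the class
    whose mean ``m`` they fall in (C = occupied intensity range), and T
    minimizes the summed Shannon entropy of the memberships. Ties go to the
    lower threshold.

Pixels strictly above the threshold are foreground (ImageJ
measure-over-threshold behavior); ``strict=False`` switches to ``>=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ThresholdResult",
    "histogram_from_image",
    "ij_default_threshold",
    "isodata_threshold",
    "huang_threshold",
    "auto_threshold",
    "masked_area",
    "area_ratio",
    "AutoThreshold",
]


@dataclass(frozen=True)
class ThresholdResult:
    """A threshold plus the area measurements made under it."""

    method: str
    threshold: float
    area_above: int
    roi_area: int
    area_above_um2: float | None = None
    roi_area_um2: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.area_above <= self.roi_area):
            raise ValueError("area_above must lie in [0, roi_area]")


def _occupied_range(hist: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(hist)[0]
    if nz.size == 0:
        raise ValueError("empty histogram")
    return int(nz[0]), int(nz[-1])


def _validate_hist(hist) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1D with at least two bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    lo, hi = _occupied_range(hist)
    if lo == hi:
        raise ValueError("single-valued histogram: no threshold separates anything")
    return hist


def histogram_from_image(
    image: np.ndarray, roi: np.ndarray | None = None, n_levels: int | None = None
) -> np.ndarray:
    """Integer-level histogram of an image, one bin per gray level.

    ``n_levels`` defaults to the image bit depth (256 for uint8, 65536 for
    uint16, else max value + 1).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    vals = image[np.asarray(roi, dtype=bool)] if roi is not None else image.ravel()
    if vals.size == 0:
        raise ValueError("ROI selects no pixels")
    if np.any(vals < 0):
        raise ValueError("negative intensities")
    if n_levels is None:
        if image.dtype == np.uint8:
            n_levels = 256
        elif image.dtype == np.uint16:
            n_levels = 65536
        else:
            n_levels = int(vals.max()) + 1
    return np.bincount(vals.astype(np.int64).ravel(), minlength=n_levels).astype(float)


def _intermeans(hist: np.ndarray, lo: int, hi: int) -> float:
    """ImageJ-style moving-index intermeans over the occupied range [lo, hi]."""
    levels = np.arange(hist.size, dtype=float)
    moving = lo
    result = float(lo)
    while True:
        below = hist[lo : moving + 1]
        above = hist[moving + 1 : hi + 1]
        s2, s4 = below.sum(), above.sum()
        if s2 == 0 or s4 == 0:
            moving += 1
            if moving >= hi:
                break
            continue
        mean_lo = (levels[lo : moving + 1] * below).sum() / s2
        mean_hi = (levels[moving + 1 : hi + 1] * above).sum() / s4
        result = (mean_lo + mean_hi) / 2.0
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return result


def ij_default_threshold(hist) -> int:
    """ImageJ "Default" threshold: intermeans with the extreme bins zeroed."""
    hist = _validate_hist(hist).copy()
    hist[0] = 0.0
    hist[-1] = 0.0
    nz = np.nonzero(hist)[0]
    if nz.size == 0 or nz[0] == nz[-1]:
        # ImageJ behavior: all mass at/near the extreme bins -> midpoint level
        return hist.size // 2
    lo, hi = int(nz[0]), int(nz[-1])
    return int(round(_intermeans(hist, lo, hi)))


def isodata_threshold(hist) -> int:
    """Classic iterative intermeans: T = round((mean<=T + mean>T)/2) at the fixed point."""
    hist = _validate_hist(hist)
    lo, hi = _occupied_range(hist)
    levels = np.arange(hist.size, dtype=float)
    t = (lo + hi) // 2
    for _ in range(hist.size + 1):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        if below.sum() == 0:
            t += 1
            continue
        if above.sum() == 0:
            t -= 1
            continue
        mean_lo = (levels[: t + 1] * below).sum() / below.sum()
        mean_hi = (levels[t + 1 :] * above).sum() / above.sum()
        new_t = int(round((mean_lo + mean_hi) / 2.0))
        if new_t == t:
            return t
        t = new_t
    return t  # cycle fallback: last iterate


def huang_threshold(hist) -> int:
    """Huang-Wang fuzzy-entropy threshold; ties break toward the lower T."""
    hist = _validate_hist(hist)
    lo, hi = _occupied_range(hist)
    c = float(hi - lo)
    levels = np.arange(hist.size, dtype=float)
    w = hist * levels
    best_t, best_obj = None, np.inf
    for t in range(lo, hi):
        s_below = hist[lo : t + 1].sum()
        s_above = hist[t + 1 : hi + 1].sum()
        if s_below == 0 or s_above == 0:
            continue
        m0 = w[lo : t + 1].sum() / s_below
        m1 = w[t + 1 : hi + 1].sum() / s_above
        g = levels[lo : hi + 1]
        m = np.where(g <= t, m0, m1)
        mu = 1.0 / (1.0 + np.abs(g - m) / c)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        entropy = -(mu * np.log(mu) + (1.0 - mu) * np.log(1.0 - mu))
        obj = float((hist[lo : hi + 1] * entropy).sum())
        if obj < best_obj - 1e-12:
            best_obj, best_t = obj, t
    if best_t is None:
        raise ValueError("no separating threshold found")
    return int(best_t)


_METHODS = {
    "default": ij_default_threshold,
    "isodata": isodata_threshold,
    "huang": huang_threshold,
}


def auto_threshold(hist, method: str = "default") -> int:
    """Dispatch to one of the named histogram threshold methods."""
    if method.startswith("fixed:"):
        return int(method.split(":", 1)[1])
    try:
        return _METHODS[method](hist)
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}; valid: {sorted(_METHODS)}")


def masked_area(
    image: np.ndarray,
    roi: np.ndarray | None,
    threshold: float,
    strict: bool = True,
    pixel_size_um: float | None = None,
    method: str = "fixed",
) -> ThresholdResult:
    """Count ROI pixels above the threshold (strictly by default)."""
    image = np.asarray(image)
    if roi is None:
        roi = np.ones(image.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError(f"ROI shape {roi.shape} != image shape {image.shape}")
    if not roi.any():
        raise ValueError("ROI selects no pixels")
    vals = image[roi]
    above = vals > threshold if strict else vals >= threshold
    area_above = int(above.sum())
    roi_area = int(roi.sum())
    px2 = None if pixel_size_um is None else float(pixel_size_um) ** 2
    return ThresholdResult(
        method=method,
        threshold=float(threshold),
        area_above=area_above,
        roi_area=roi_area,
        area_above_um2=None if px2 is None else area_above * px2,
        roi_area_um2=None if px2 is None else roi_area * px2,
    )


def area_ratio(numerator: ThresholdResult, denominator: ThresholdResult) -> float:
    """Ratio of thresholded areas, e.g. transcript signal per smooth-muscle area."""
    if denominator.area_above <= 0:
        raise ValueError("denominator area_above must be positive")
    return numerator.area_above / denominator.area_above


class AutoThreshold(BaseEstimator):
    """Estimator facade: fit computes ``threshold_`` from an image or histogram.

    Parameters
    ----------
    method : {"default", "isodata", "huang"} or "fixed:N"
    strict : bool
        Foreground is > threshold when True (ImageJ behavior), >= otherwise.
    """

    def __init__(self, method: str = "default", strict: bool = True):
        self.method = method
        self.strict = strict

    def fit(self, X: np.ndarray, y=None, roi: np.ndarray | None = None) -> "AutoThreshold":
        X = np.asarray(X)
        hist = X if X.ndim == 1 else histogram_from_image(X, roi)
        self.threshold_ = auto_threshold(hist, self.method)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean foreground mask of an image under the fitted threshold."""
        X = np.asarray(X)
        return X > self.threshold_ if self.strict else X >= self.threshold_

    def measure(
        self,
        image: np.ndarray,
        roi: np.ndarray | None = None,
        pixel_size_um: float | None = None,
    ) -> ThresholdResult:
        return masked_area(
            image, roi, self.threshold_, strict=self.strict,
            pixel_size_um=pixel_size_um, method=self.method,
        )
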