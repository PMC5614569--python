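"""Vessel-mask generation by Otsu thresholding and time–density extraction.

The spatial map of an ICA component is clipped to non-negative values
(only positive loading indicates contrast arrival under the fixed sign
convention), thresholded by between-class variance maximization, and the
resulting binary mask is multiplied into the registered series pixel by
pixel to yield the phase's time–density curve (TDC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import DSASeries, TimeGrid, ValidationError

__all__ = ["VesselMask", "TDC", "otsu_threshold", "make_mask", "extract_tdc"]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 256


@dataclass
class VesselMask:
    """Binary vessel mask for one phase with the Otsu cut that produced it."""

    mask: np.ndarray
    phase: str
    threshold: float
    fraction_on: float
    degenerate: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TDC:
    """Time–density curve: per-frame contrast density aggregated over a mask.

    ``density`` is the mean over masked pixels (arbitrary units), matching
    the grid frame for frame. Under the baseline-subtracted convention the
    value at t = 0 is ~0.
    """

    grid: TimeGrid
    density: np.ndarray
    label: str
    n_pixels: int

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 1 or d.size != len(self.grid):
            raise ValidationError("density length must match grid")
        if not np.all(np.isfinite(d)):
            raise ValidationError("non-finite density value")
        self.density = d


def otsu_threshold(values: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Between-class variance maximizing threshold over equal-width bins.

    Values are histogrammed into ``n_bins`` equal-width bins over
    [min, max]; candidate cuts are the interior bin edges, classifying
    values as below / at-or-above the edge. The edge maximizing
    w0*w1*(mu0-mu1)^2 is returned; ties take the lowest edge.

    Raises for fewer than 2 distinct values (no cut can separate anything).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValidationError("need >= 2 finite values")
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValidationError("all values equal; no threshold exists")

    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    sums, _ = np.histogram(v, bins=n_bins, range=(lo, hi), weights=v)
    n = v.size
    w0 = np.cumsum(counts)[:-1]            # class 0 size at each interior edge
    s0 = np.cumsum(sums)[:-1]
    w1 = n - w0
    s1 = v.sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(n_bins - 1)
    sigma_b[valid] = (w0[valid] / n) * (w1[valid] / n) * \
        (s0[valid] / w0[valid] - s1[valid] / w1[valid]) ** 2
    best = int(np.argmax(sigma_b))         # argmax returns the first (lowest) tie
    return float(edges[1:-1][best])


def make_mask(spatial_map: np.ndarray, phase: str,
              n_bins: int = DEFAULT_BINS) -> VesselMask:
    """Binarize a component's spatial map: clip negatives to 0, Otsu cut,
    keep pixels strictly above the cut.

    A constant (e.g. all-negative) clipped map cannot be thresholded and
    yields an all-off mask flagged degenerate.
    """
    m = np.asarray(spatial_map, dtype=float)
    if m.ndim != 2:
        raise ValidationError("spatial map must be 2-D")
    if not np.all(np.isfinite(m)):
        raise ValidationError("non-finite map value")
    clipped = np.clip(m, 0.0, None)
    if clipped.min() == clipped.max():
        logger.warning("constant clipped map for phase %s; degenerate mask", phase)
        return VesselMask(mask=np.zeros(m.shape, dtype=bool), phase=phase,
                          threshold=float(clipped.min()), fraction_on=0.0,
                          degenerate=True)
    thr = otsu_threshold(clipped.ravel(), n_bins=n_bins)
    mask = clipped > thr
    frac = float(mask.mean())
    degenerate = not mask.any()
    if degenerate:
        logger.warning("empty mask for phase %s", phase)
    return VesselMask(mask=mask, phase=phase, threshold=thr,
                      fraction_on=frac, degenerate=degenerate)


def extract_tdc(series: DSASeries, mask: VesselMask) -> TDC:
    """Mean contrast density over the masked pixels, frame by frame.

    The mean (rather than the sum) keeps curves comparable across views
    and mask sizes; the FWHM-derived transit time is invariant to the
    vertical scale either way.
    """
    if mask.degenerate or not mask.mask.any():
        raise ValidationError("degenerate mask; no TDC can be extracted")
    if mask.mask.shape != series.frames.shape[1:]:
        raise ValidationError(
            f"mask shape {mask.mask.shape} != frame shape {series.frames.shape[1:]}")
    density = series.frames[:, mask.mask].mean(axis=1)
    return TDC(grid=series.grid, density=density, label=mask.phase,
               n_pixels=mask.n_pixels)


def mask_to_png(mask: VesselMask, path) -> None:
    """Export a mask as an 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def tdc_to_csv(tdc: TDC, path) -> None:
    """Export a TDC as CSV with columns ``t_s,density``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "density"])
        for t, d in zip(tdc.grid.timestamps, tdc.density):
            writer.writerow([repr(float(t)), repr(float(d))])
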