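"""Three-source independent component decomposition of a DSA series.

Frames are flattened into a (T x H*W) data matrix and decomposed with
FastICA into exactly three components. The decomposition is run spatially:
the spatial maps are the independent sources (vascular territories overlap
little, so their pixel supports are close to statistically independent and
strongly super-Gaussian), and the time courses are the paired mixing
columns. After resolving the sign ambiguity, components are labelled
arterial / capillary / venous by the time of their time-course maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import DSASeries, TimeGrid, ValidationError

__all__ = ["ComponentSet", "PHASES", "flatten_series", "unflatten_map",
           "decompose", "fix_signs", "assign_phases", "detect_two_peaks"]

logger = logging.getLogger(__name__)

PHASES = ("arterial", "capillary", "venous")


@dataclass
class ComponentSet:
    """Result of the 3-source decomposition.

    ``spatial_maps`` is (3, H, W) component weight per pixel,
    ``time_courses`` (3, T) component activation per frame, and
    ``mean_course`` the per-frame spatial mean removed by centering, so
    that ``data ~ mean_course[:, None] + sum_k course_k (x) map_k``.
    ``phase_labels`` is a permutation of
    ``("arterial", "capillary", "venous")`` once assigned.
    """

    spatial_maps: np.ndarray
    time_courses: np.ndarray
    mean_course: np.ndarray
    phase_labels: Optional[tuple[str, str, str]] = None
    converged: bool = True
    n_iter: int = 0
    tol: float = 1e-4
    seed: Optional[int] = None
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spatial_maps.shape[0] != 3 or self.time_courses.shape[0] != 3:
            raise ValidationError("exactly 3 components required")
        if self.phase_labels is not None and sorted(self.phase_labels) != sorted(PHASES):
            raise ValidationError("phase_labels must be a permutation of the 3 phases")

    @property
    def n_frames(self) -> int:
        return self.time_courses.shape[1]

    def map_for(self, phase: str) -> np.ndarray:
        """Spatial map of the component labelled ``phase``."""
        return self.spatial_maps[self._index_of(phase)]

    def course_for(self, phase: str) -> np.ndarray:
        return self.time_courses[self._index_of(phase)]

    def _index_of(self, phase: str) -> int:
        if self.phase_labels is None:
            raise ValidationError("phases not assigned yet")
        return self.phase_labels.index(phase)

    def reconstruct(self) -> np.ndarray:
        """Centered-data reconstruction: (T, H*W) without the mean map."""
        maps_flat = self.spatial_maps.reshape(3, -1)
        return self.time_courses.T @ maps_flat


def flatten_series(series: DSASeries) -> tuple[np.ndarray, tuple[int, int]]:
    """Permute the 2-D frames into per-frame 1-D signals.

    Returns the (T, H*W) data matrix (row t = frame t in row-major pixel
    order) and the (H, W) shape needed to un-flatten spatial maps.
    """
    t, h, w = series.frames.shape
    return series.frames.reshape(t, h * w), (h, w)


def unflatten_map(flat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of the pixel flattening for a single spatial map."""
    return np.asarray(flat).reshape(shape)


def decompose(data: np.ndarray, shape: tuple[int, int], n_components: int = 3,
              seed: int = 0, max_iter: int = 500, tol: float = 1e-4,
              ) -> ComponentSet:
    """FastICA estimation: center, whiten to ``n_components`` principal
    directions, then fixed-point iteration with the log-cosh contrast.

    The pixel dimension carries the independence assumption: FastICA sees
    one sample per pixel (its frame-wise intensities as features), so the
    recovered sources are the spatial maps and the mixing columns the
    time courses. Deterministic given ``seed``. Non-convergence within
    ``max_iter`` is flagged (``converged=False``) and warned about, never
    raised.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data matrix must be 2-D (T x pixels)")
    if data.shape[0] < n_components:
        raise ValidationError(
            f"need at least {n_components} frames, got {data.shape[0]}")
    if not np.all(np.isfinite(data)):
        raise ValidationError("data matrix contains non-finite values")
    if n_components != 3:
        raise ValidationError("component count is fixed at 3 (arterial/capillary/venous)")

    # explicit whitening: center each frame over pixels, project onto the
    # top-3 principal directions, scale to unit variance. Done by hand
    # rather than inside FastICA so that exactly rank-deficient input
    # (noiseless synthetic data) degrades cleanly instead of poisoning the
    # decomposition with divisions by vanishing singular values.
    n_pixels = data.shape[1]
    pixels_by_frame = data.T                        # (pixels, T)
    mean_course = pixels_by_frame.mean(axis=0)
    centered = pixels_by_frame - mean_course
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    converged = True
    msgs: list[str] = []
    if sv[n_components - 1] <= 1e-10 * max(sv[0], 1e-300):
        converged = False
        msgs.append(f"data rank < {n_components}; degenerate components")
        logger.warning(msgs[-1])
    sv_floor = np.maximum(sv[:n_components], 1e-12 * max(sv[0], 1e-300))
    whitener = vt[:n_components] / sv_floor[:, None]        # (3, T)
    whitened = centered @ whitener.T * np.sqrt(n_pixels)    # (pixels, 3)

    ica = FastICA(n_components=n_components, fun="logcosh", algorithm="parallel",
                  whiten=False, max_iter=max_iter, tol=tol,
                  random_state=int(seed))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(whitened)       # (pixels, 3) spatial sources
    for wmsg in caught:
        if issubclass(wmsg.category, ConvergenceWarning):
            converged = False
            msgs.append(str(wmsg.message))
            logger.warning("FastICA did not converge: %s", wmsg.message)

    maps = sources.T.reshape(n_components, *shape).copy()
    unmix = ica.components_ @ whitener * np.sqrt(n_pixels)  # sources = unmix @ centered.T
    courses = np.linalg.pinv(unmix).T.copy()                # (3, T) mixing columns
    return ComponentSet(spatial_maps=maps, time_courses=courses,
                        mean_course=mean_course.copy(),
                        converged=converged, n_iter=int(ica.n_iter_),
                        tol=tol, seed=int(seed), warnings_=msgs)


def fix_signs(components: ComponentSet) -> ComponentSet:
    """Resolve the ICA sign ambiguity.

    Each component is multiplied by +-1 so its time course's maximum
    exceeds the absolute value of its minimum; the spatial map is flipped
    with it, leaving the reconstruction unchanged.
    """
    courses = components.time_courses.copy()
    maps = components.spatial_maps.copy()
    for k in range(3):
        if courses[k].max() < -courses[k].min():
            courses[k] = -courses[k]
            maps[k] = -maps[k]
    return ComponentSet(spatial_maps=maps, time_courses=courses,
                        mean_course=components.mean_course,
                        phase_labels=components.phase_labels,
                        converged=components.converged, n_iter=components.n_iter,
                        tol=components.tol, seed=components.seed,
                        warnings_=list(components.warnings_))


def assign_phases(components: ComponentSet, grid: TimeGrid) -> ComponentSet:
    """Label components arterial / capillary / venous by time to peak.

    Components are ordered by the timestamp of their time-course maximum:
    earliest -> arterial, middle -> capillary, latest -> venous. TTP ties
    are broken by larger spatial-map energy taking the earlier phase; a
    full tie falls back to component index (with a warning).
    """
    if components.time_courses.shape[1] != len(grid):
        raise ValidationError("grid length does not match time courses")
    ts = grid.timestamps
    ttps = ts[np.argmax(components.time_courses, axis=1)]
    energy = np.sum(components.spatial_maps.reshape(3, -1) ** 2, axis=1)
    order = sorted(range(3), key=lambda k: (ttps[k], -energy[k], k))
    for a, b in ((0, 1), (1, 2)):
        ka, kb = order[a], order[b]
        if ttps[ka] == ttps[kb] and energy[ka] == energy[kb]:
            logger.warning("components %d and %d tie on TTP and energy; "
                           "index order used", ka, kb)
    labels = [""] * 3
    for phase, k in zip(PHASES, order):
        labels[k] = phase
    out = ComponentSet(spatial_maps=components.spatial_maps,
                       time_courses=components.time_courses,
                       mean_course=components.mean_course,
                       phase_labels=tuple(labels),
                       converged=components.converged, n_iter=components.n_iter,
                       tol=components.tol, seed=components.seed,
                       warnings_=list(components.warnings_))
    return out


def detect_two_peaks(density: np.ndarray, rel_height: float = 0.3,
                     rel_prominence: float = 0.2) -> bool:
    """Flag a curve with two distinguishable peaks.

    Used on the capillary TDC: stagnant arterial flow at severe stenosis
    can leak arterial signal into the capillary component, producing a
    second bump. A peak counts when it rises above ``rel_height`` of the
    global maximum with prominence above ``rel_prominence`` of it.
    """
    d = np.asarray(density, dtype=float)
    peak = d.max()
    if peak <= 0:
        return False
    idx, _ = find_peaks(d, height=rel_height * peak,
                        prominence=rel_prominence * peak)
    return len(idx) >= 2
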