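"""Keypoint-based rigid motion correction.

Every frame of a series is aligned to the reference frame at t = 0 using
scale/rotation-invariant keypoints (SIFT), a Lowe ratio test, and a robust
RANSAC fit of a rigid (rotation + translation) transform. Early
contrast-free frames that yield too few matches inherit the transform of
the nearest later frame that registered successfully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import EuclideanTransform, warp

from .io import DSASeries, ValidationError

__all__ = ["RigidTransform", "estimate_transform", "register_series",
           "transforms_to_csv"]

logger = logging.getLogger(__name__)

#: matches below this count give up and return identity
DEFAULT_MIN_MATCHES = 8
#: Lowe-style nearest/second-nearest descriptor ratio
LOWE_RATIO = 0.75
#: RANSAC inlier tolerance, pixels
INLIER_TOL_PX = 1.0
#: SIFT difference-of-Gaussian contrast threshold. Much lower than the
#: detector default: frames are normalized by their peak, and once contrast
#: fills the vessels the faint subtraction-residual anatomy — the only
#: texture shared with the t = 0 reference — sits at a few percent of that
#: peak and must still yield keypoints.
SIFT_C_DOG = 0.001


@dataclass
class RigidTransform:
    """Rigid map from reference coordinates to moving-frame coordinates.

    ``rotation_deg`` and ``(dx_px, dy_px)`` parameterize an (x, y)-plane
    Euclidean transform about the origin; ``success`` is False when the
    identity fallback was used; ``inherited`` marks transforms copied from
    a neighbouring frame.
    """

    rotation_deg: float = 0.0
    dx_px: float = 0.0
    dy_px: float = 0.0
    success: bool = True
    inherited: bool = False
    n_matches: int = 0

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > 45:
            raise ValidationError(
                f"rotation {self.rotation_deg:.1f} deg outside sanity bound 45 deg")

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.dx_px == 0.0 and self.dy_px == 0.0

    def to_skimage(self) -> EuclideanTransform:
        return EuclideanTransform(rotation=np.deg2rad(self.rotation_deg),
                                  translation=(self.dx_px, self.dy_px))

    @classmethod
    def from_skimage(cls, tf: EuclideanTransform, **kw) -> "RigidTransform":
        return cls(rotation_deg=float(np.rad2deg(tf.rotation)),
                   dx_px=float(tf.translation[0]),
                   dy_px=float(tf.translation[1]), **kw)

    def mean_displacement(self, shape: tuple[int, int]) -> float:
        """Mean displacement magnitude the transform induces over a frame."""
        h, w = shape
        yy, xx = np.mgrid[0:h:8, 0:w:8]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        moved = self.to_skimage()(pts)
        return float(np.mean(np.linalg.norm(moved - pts, axis=1)))


def _detect(frame: np.ndarray, detector: SIFT) -> tuple[np.ndarray, np.ndarray]:
    peak = np.abs(frame).max()
    img = frame / peak if peak > 0 else frame
    try:
        detector.detect_and_extract(img)
    except RuntimeError:  # no features found
        return np.empty((0, 2)), np.empty((0, 128))
    return detector.keypoints.copy(), detector.descriptors.copy()


def estimate_transform(moving: np.ndarray, reference: np.ndarray,
                       min_matches: int = DEFAULT_MIN_MATCHES,
                       _ref_features: tuple[np.ndarray, np.ndarray] | None = None,
                       ) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Returns the identity with ``success=False`` (and a logged warning) when
    either frame yields fewer than ``min_matches`` ratio-test survivors —
    degenerate, not an error, because early contrast-free subtraction
    frames legitimately carry no texture.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValidationError(
            f"shape mismatch: moving {moving.shape} vs reference {reference.shape}")

    detector = SIFT(c_dog=SIFT_C_DOG)
    if _ref_features is None:
        _ref_features = _detect(reference, detector)
    ref_kp, ref_desc = _ref_features
    mov_kp, mov_desc = _detect(moving, detector)
    if len(ref_kp) < min_matches or len(mov_kp) < min_matches:
        logger.warning("insufficient keypoints (%d ref, %d moving); identity used",
                       len(ref_kp), len(mov_kp))
        return RigidTransform(success=False, n_matches=0)

    matches = match_descriptors(ref_desc, mov_desc, max_ratio=LOWE_RATIO,
                                cross_check=True)
    if len(matches) < min_matches:
        logger.warning("only %d matches (< %d); identity used",
                       len(matches), min_matches)
        return RigidTransform(success=False, n_matches=len(matches))

    # keypoints are (row, col); transforms operate on (x, y)
    src = ref_kp[matches[:, 0]][:, ::-1]
    dst = mov_kp[matches[:, 1]][:, ::-1]
    model, inliers = ransac((src, dst), EuclideanTransform, min_samples=2,
                            residual_threshold=INLIER_TOL_PX, max_trials=500,
                            rng=0)
    if model is None or inliers is None or inliers.sum() < min_matches:
        logger.warning("RANSAC consensus too small; identity used")
        return RigidTransform(success=False, n_matches=len(matches))
    try:
        return RigidTransform.from_skimage(model, n_matches=int(inliers.sum()))
    except ValidationError:
        logger.warning("estimated transform outside sanity bounds; identity used")
        return RigidTransform(success=False, n_matches=int(inliers.sum()))


def register_series(series: DSASeries, min_matches: int = DEFAULT_MIN_MATCHES,
                    ) -> tuple[DSASeries, list[RigidTransform]]:
    """Resample every frame t > 0 into the t = 0 reference coordinates.

    Frames whose matching fails inherit the transform of the nearest later
    frame that registered successfully (contrast-free early frames carry
    the same patient pose as the frames just after them), else identity.
    Bilinear interpolation; out-of-bounds pixels are 0 density.
    """
    frames = series.frames
    n = frames.shape[0]
    if n == 1:
        return series, []

    detector = SIFT(c_dog=SIFT_C_DOG)
    ref_idx = 0
    ref_features = _detect(frames[0], detector)
    if len(ref_features[0]) < min_matches:
        # exact baseline subtraction can leave the t = 0 reference with no
        # texture at all; fall back to the earliest feature-rich frame as a
        # surrogate reference — pre-bolus frames share the reference pose
        # because motion accumulates over the acquisition
        for t in range(1, n):
            cand = _detect(frames[t], detector)
            if len(cand[0]) >= min_matches:
                ref_idx, ref_features = t, cand
                logger.warning("t=0 reference featureless; frame %d used as "
                               "surrogate reference", t)
                break
    transforms: list[RigidTransform] = [RigidTransform(n_matches=0)
                                        for _ in range(ref_idx + 1)]
    for t in range(ref_idx + 1, n):
        transforms.append(estimate_transform(frames[t], frames[ref_idx],
                                             min_matches,
                                             _ref_features=ref_features))
    # fill failures from the nearest later success
    next_ok: RigidTransform | None = None
    for t in range(n - 1, 0, -1):
        if transforms[t].success:
            next_ok = transforms[t]
        elif next_ok is not None:
            transforms[t] = RigidTransform(
                rotation_deg=next_ok.rotation_deg, dx_px=next_ok.dx_px,
                dy_px=next_ok.dy_px, success=False, inherited=True,
                n_matches=transforms[t].n_matches)

    out = frames.copy()
    for t in range(1, n):
        tf = transforms[t]
        if not tf.is_identity:
            out[t] = warp(frames[t], tf.to_skimage(), order=1, cval=0.0,
                          preserve_range=True)
    registered = DSASeries(frames=out, grid=series.grid, view=series.view,
                           polarity_note=series.polarity_note)
    return registered, transforms


def transforms_to_csv(transforms: list[RigidTransform], path) -> None:
    """Export per-frame transforms as ``frame,rotation_deg,dx_px,dy_px``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "rotation_deg", "dx_px", "dy_px"])
        for i, tf in enumerate(transforms):
            writer.writerow([i, tf.rotation_deg, tf.dx_px, tf.dy_px])
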