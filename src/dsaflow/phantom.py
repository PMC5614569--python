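"""Synthetic biplane DSA phantom with known ground truth.

A phantom emulates a contrast bolus passing through spatially overlapping
arterial (vessel tree), capillary (parenchymal blush) and venous
compartments, each with gamma-variate kinetics, sampled on the multi-rate
clinical schedule. Compartments superpose additively (projection physics:
densities add along a ray), per-pixel lognormal amplitude jitter makes the
maps non-binary, and optional Gaussian noise, Poisson scaling, rigid
per-frame motion and a static subtraction-residual background complete the
model. Every stage of the analysis pipeline can be checked against the
returned ground-truth bundle.

Geometry is specified in unit coordinates ([0, 1] x [0, 1], x right,
y down) and scaled to the frame, so phantoms are resolution-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse
from skimage.transform import warp

from .io import AcquisitionSchedule, DSASeries, TimeGrid, ValidationError, \
    build_time_grid
from .markers import fwhm_factor, gamma_variate
from .registration import RigidTransform

__all__ = ["CompartmentSpec", "PhantomSpec", "PhantomTruth",
           "generate_phantom", "standard_phantom", "default_schedule"]


def default_schedule(extension_duration: float = 0.0) -> AcquisitionSchedule:
    """The clinical acquisition schedule: 7.5 fps x 5 s, 4 x 3, 3 x 2,
    2 x 2 (12 s base), optionally prolonged at 2 fps."""
    return AcquisitionSchedule.default(extension_duration=extension_duration)


@dataclass(frozen=True)
class CompartmentSpec:
    """One vascular compartment: geometry plus gamma-variate kinetics.

    ``geometry`` kinds: ``{"kind": "polylines", "paths": [[(x,y),...],...],
    "width": w}`` (vessel tree, unit coords, width as fraction of the
    short frame side) or ``{"kind": "ellipse", "center": (x,y),
    "axes": (rx, ry)}`` (blush region). ``kinetics`` is (t0, alpha, beta,
    K); ``jitter`` the lognormal sigma of per-pixel amplitude."""

    phase: str
    geometry: dict
    kinetics: tuple[float, float, float, float]
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in ("arterial", "capillary", "venous"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        t0, alpha, beta, K = self.kinetics
        if not (alpha > 0 and beta > 0 and K > 0):
            raise ValidationError("kinetics require alpha, beta, K > 0")
        if self.geometry.get("kind") not in ("polylines", "ellipse"):
            raise ValidationError("geometry kind must be 'polylines' or 'ellipse'")

    @property
    def ttp(self) -> float:
        t0, alpha, beta, _ = self.kinetics
        return t0 + alpha * beta

    @property
    def fwhm(self) -> float:
        _, alpha, beta, _ = self.kinetics
        return beta * fwhm_factor(alpha)

    def course(self, grid: TimeGrid) -> np.ndarray:
        """Exact analytic time course on the grid."""
        t0, alpha, beta, K = self.kinetics
        return gamma_variate(grid.timestamps, t0, alpha, beta, K)


@dataclass(frozen=True)
class PhantomSpec:
    """Full ground-truth description of a synthetic acquisition."""

    shape: tuple[int, int] = (128, 128)
    schedule: AcquisitionSchedule = field(default_factory=default_schedule)
    compartments: tuple[CompartmentSpec, ...] = ()
    noise_sigma: float = 0.0          # Gaussian s.d. as fraction of global peak
    poisson_scale: float = 0.0        # photons per density unit; 0 disables
    background: float = 0.0           # static residual amplitude, fraction of peak
    motion: Optional[tuple[RigidTransform, ...]] = None  # per-frame pose
    seed: int = 0
    view: str = "AP"

    def __post_init__(self) -> None:
        if len(self.compartments) == 0:
            raise ValidationError("phantom needs at least one compartment")
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if self.noise_sigma < 0 or self.background < 0 or self.poisson_scale < 0:
            raise ValidationError("noise, background and poisson_scale must be >= 0")

    def with_noise(self, sigma: float) -> "PhantomSpec":
        return replace(self, noise_sigma=sigma)

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass
class PhantomTruth:
    """Ground truth bundle: per-compartment rasters, exact courses, TTP and
    FWHM, plus the motion schedule actually applied."""

    rasters: dict[str, np.ndarray]          # phase -> bool support mask
    amplitude_maps: dict[str, np.ndarray]   # phase -> jittered amplitude raster
    courses: dict[str, np.ndarray]          # phase -> analytic course on grid
    ttp: dict[str, float]
    fwhm: dict[str, float]
    motion: list[RigidTransform]
    spec: PhantomSpec

    def to_json(self, path) -> None:
        doc = {
            "ttp_s": self.ttp,
            "fwhm_s": self.fwhm,
            "kinetics": {c.phase: dict(zip(("t0", "alpha", "beta", "K"),
                                           c.kinetics))
                         for c in self.spec.compartments},
            "motion": [{"frame": i, "rotation_deg": m.rotation_deg,
                        "dx_px": m.dx_px, "dy_px": m.dy_px}
                       for i, m in enumerate(self.motion)],
            "seed": self.spec.seed,
            "view": self.spec.view,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _rasterize(comp: CompartmentSpec, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    scale = min(h, w)
    canvas = np.zeros(shape, dtype=bool)
    g = comp.geometry
    if g["kind"] == "ellipse":
        cx, cy = g["center"]
        rx, ry = g["axes"]
        rr, cc = ellipse(cy * h, cx * w, ry * h, rx * w, shape=shape)
        canvas[rr, cc] = True
    else:
        radius = max(1.0, 0.5 * g["width"] * scale)
        for path in g["paths"]:
            pts = np.asarray(path, dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 2:
                raise ValidationError("polyline needs >= 2 points")
            for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
                seg_len = np.hypot((x1 - x0) * w, (y1 - y0) * h)
                n = max(2, int(np.ceil(seg_len)) + 1)
                for f in np.linspace(0.0, 1.0, n):
                    x = (x0 + f * (x1 - x0)) * w
                    y = (y0 + f * (y1 - y0)) * h
                    rr, cc = disk((y, x), radius, shape=shape)
                    canvas[rr, cc] = True
    if not canvas.any():
        raise ValidationError(
            f"compartment {comp.phase!r} rasterizes to nothing (out of bounds?)")
    return canvas


def generate_phantom(spec: PhantomSpec) -> tuple[DSASeries, PhantomTruth]:
    """Render the phantom series and its ground-truth bundle.

    frame(t) = sum_c raster_c * gamma_variate(t; kinetics_c) + background,
    then per-frame rigid motion (if scheduled), then noise. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    grid = build_time_grid(spec.schedule)
    n_frames = len(grid)

    rasters: dict[str, np.ndarray] = {}
    amps: dict[str, np.ndarray] = {}
    courses: dict[str, np.ndarray] = {}
    ttp: dict[str, float] = {}
    fwhm: dict[str, float] = {}
    stack = np.zeros((n_frames, h, w))
    for comp in spec.compartments:
        raster = _rasterize(comp, (h, w))
        amp = raster.astype(float)
        if comp.jitter > 0:
            amp = amp * rng.lognormal(mean=0.0, sigma=comp.jitter, size=(h, w))
            amp[~raster] = 0.0
        course = comp.course(grid)
        stack += course[:, None, None] * amp[None]
        key = comp.phase
        if key in rasters:  # multiple compartments per phase: union/sum
            rasters[key] |= raster
            amps[key] = amps[key] + amp
            courses[key] = courses[key] + course
        else:
            rasters[key], amps[key], courses[key] = raster, amp, course
        ttp[key] = comp.ttp
        fwhm[key] = comp.fwhm

    peak = float(stack.max())
    if spec.background > 0:
        # static subtraction-residual anatomy: smoothed noise field with edges
        bg = gaussian_filter(rng.normal(size=(h, w)), 1.5)
        bg -= bg.min()
        bg *= spec.background * peak / bg.max()
        stack += bg[None]

    motion: list[RigidTransform]
    if spec.motion is not None:
        motion = list(spec.motion)
        if len(motion) != n_frames:
            raise ValidationError(
                f"motion schedule length {len(motion)} != frame count {n_frames}")
        for t, pose in enumerate(motion):
            if not pose.is_identity:
                # pose maps reference coords -> frame-content source coords;
                # rendering applies the inverse so that registering with the
                # estimated pose restores the reference geometry
                stack[t] = warp(stack[t],
                                pose.to_skimage().inverse, order=1,
                                cval=0.0, preserve_range=True)
    else:
        motion = [RigidTransform() for _ in range(n_frames)]

    if spec.noise_sigma > 0:
        stack = stack + rng.normal(0.0, spec.noise_sigma * peak, size=stack.shape)
    if spec.poisson_scale > 0:
        lam = np.clip(stack, 0.0, None) * spec.poisson_scale
        stack = rng.poisson(lam).astype(float) / spec.poisson_scale

    series = DSASeries(frames=stack, grid=grid, view=spec.view)
    truth = PhantomTruth(rasters=rasters, amplitude_maps=amps, courses=courses,
                         ttp=ttp, fwhm=fwhm, motion=motion, spec=spec)
    return series, truth


def _amplitude(alpha: float, beta: float, peak: float) -> float:
    """K that puts the gamma-variate peak at ``peak`` density units."""
    return peak / ((alpha * beta) ** alpha * np.exp(-alpha))


def _vessel_tree(side: str) -> list[list[tuple[float, float]]]:
    """A branching carotid-like tree in unit coordinates."""
    if side == "left":
        return [
            [(0.08, 0.95), (0.10, 0.60), (0.16, 0.35), (0.22, 0.12)],
            [(0.13, 0.47), (0.24, 0.40), (0.34, 0.30)],
            [(0.10, 0.60), (0.20, 0.62), (0.30, 0.58)],
        ]
    return [
        [(0.92, 0.95), (0.90, 0.62), (0.84, 0.35), (0.76, 0.10)],
        [(0.87, 0.48), (0.76, 0.44), (0.66, 0.34)],
        [(0.90, 0.62), (0.80, 0.68), (0.70, 0.64)],
    ]


def _capillary_kinetics(ttp: float = 4.5, fwhm_target: float = 5.0,
                        alpha: float = 3.0, peak: float = 0.6,
                        ) -> tuple[float, float, float, float]:
    beta = fwhm_target / fwhm_factor(alpha)
    t0 = ttp - alpha * beta
    return (t0, alpha, beta, _amplitude(alpha, beta, peak))


def standard_phantom(name: str, seed: int = 0, shape: tuple[int, int] = (128, 128),
                     noise_sigma: float = 0.0, view: str = "AP",
                     ) -> PhantomSpec:
    """Named phantom configurations used throughout validation.

    ``easy``
        Spatially disjoint compartments with TTPs 2 / 4.5 / 7 s and a
        ground-truth capillary FWHM of 5.0 s.
    ``overlap``
        The capillary blush enlarged to overlap the arterial tree by
        ~20% of its pixels.
    ``severe_stenosis_like``
        Arterial scale inflated so the arterial and capillary time courses
        correlate >= 0.7 — the stagnant-flow stress case where arteries
        leak into the capillary component.
    ``motion``
        ``easy`` plus smooth rigid motion (<= 5 px translation, <= 2 deg)
        and a static subtraction-residual background for the keypoint
        matcher to lock onto.
    """
    jit = 0.25
    arterial = CompartmentSpec(
        phase="arterial",
        geometry={"kind": "polylines", "paths": _vessel_tree("left"),
                  "width": 0.035},
        kinetics=(0.8, 4.0, 0.3, _amplitude(4.0, 0.3, 1.0)), jitter=jit)
    capillary = CompartmentSpec(
        phase="capillary",
        geometry={"kind": "ellipse", "center": (0.62, 0.40),
                  "axes": (0.17, 0.22)},
        kinetics=_capillary_kinetics(), jitter=jit)
    venous = CompartmentSpec(
        phase="venous",
        geometry={"kind": "polylines",
                  "paths": [[(0.30, 0.88), (0.55, 0.92), (0.80, 0.88)],
                            [(0.55, 0.92), (0.56, 0.75)]],
                  "width": 0.045},
        kinetics=(4.0, 3.0, 1.0, _amplitude(3.0, 1.0, 0.8)), jitter=jit)

    if view == "LAT":  # independent layout, shared kinetics
        arterial = replace(arterial, geometry={
            "kind": "polylines", "paths": _vessel_tree("right"), "width": 0.035})
        capillary = replace(capillary, geometry={
            "kind": "ellipse", "center": (0.38, 0.42), "axes": (0.18, 0.20)})
        venous = replace(venous, geometry={
            "kind": "polylines",
            "paths": [[(0.15, 0.86), (0.40, 0.90), (0.68, 0.86)],
                      [(0.40, 0.90), (0.42, 0.72)]],
            "width": 0.045})

    base = dict(shape=shape, schedule=default_schedule(), seed=seed, view=view,
                noise_sigma=noise_sigma, background=0.04)

    if name == "easy":
        return PhantomSpec(compartments=(arterial, capillary, venous), **base)
    if name == "overlap":
        # blush shifted onto the arterial tree: ~20% of its pixels overlap
        cap = replace(capillary, geometry={
            "kind": "ellipse",
            "center": (0.22, 0.45) if view == "AP" else (0.80, 0.45),
            "axes": (0.20, 0.28)})
        return PhantomSpec(compartments=(arterial, cap, venous), **base)
    if name == "severe_stenosis_like":
        # stagnant arterial flow mimicking the parenchymal blush: slow broad
        # washout (course correlates >= 0.7 with the capillary course) and
        # the blush shifted under the arterial tree (projection overlap)
        art = replace(arterial,
                      kinetics=(1.0, 3.0, 1.2, _amplitude(3.0, 1.2, 1.0)))
        cap = replace(capillary, geometry={
            "kind": "ellipse",
            "center": (0.22, 0.45) if view == "AP" else (0.80, 0.45),
            "axes": (0.20, 0.28)})
        return PhantomSpec(compartments=(art, cap, venous), **base)
    if name == "motion":
        grid = build_time_grid(default_schedule())
        rng = np.random.default_rng(seed + 7919)
        n = len(grid)
        # smooth random pose path, frame 0 at identity
        def smooth_path(scale):
            steps = rng.normal(0.0, 1.0, size=n)
            path = np.cumsum(steps)
            path -= path[0]
            m = np.abs(path).max()
            return path / m * scale if m > 0 else path
        dx = smooth_path(4.0)
        dy = smooth_path(4.0)
        rot = smooth_path(1.5)
        poses = tuple(RigidTransform(rotation_deg=float(rot[i]),
                                     dx_px=float(dx[i]), dy_px=float(dy[i]))
                      for i in range(n))
        return PhantomSpec(compartments=(arterial, capillary, venous),
                           motion=poses, **base)
    raise ValidationError(f"unknown phantom name {name!r}")
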