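"""Hemodynamic markers from time–density curves.

The bolus passage through a compartment is modelled by the gamma-variate
indicator-dilution form

    C(t) = baseline + K (t - t0)^alpha exp(-(t - t0)/beta)   for t > t0,
    C(t) = baseline                                           otherwise,

with arrival delay t0 (s), shape alpha (> 0), scale beta (s, > 0) and
amplitude K. Analytic identities used throughout:

    TTP  = t0 + alpha * beta
    FWHM = beta * w(alpha),   w depending only on alpha.

The angiographic mean transit time (aMTT) is the FWHM of the capillary
component's TDC; the cerebral circulation time (CCT) is the TTP difference
between a parietal-vein ROI and a cavernous internal-carotid ROI on a
lateral view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import pearsonr

from .io import DSASeries, ROISet, TimeGrid, ValidationError
from .ica import ComponentSet, assign_phases, decompose, detect_two_peaks, \
    fix_signs, flatten_series
from .registration import RigidTransform, register_series
from .segmentation import TDC, VesselMask, extract_tdc, make_mask

__all__ = [
    "GammaVariateFit", "CCTResult", "AMTTResult", "FitError",
    "gamma_variate", "fit_gamma_variate", "compute_fwhm", "fwhm_factor",
    "compute_ttp", "compute_amtt", "compute_cct", "correlate_markers",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a TDC cannot support a gamma-variate fit."""


def gamma_variate(t, t0: float, alpha: float, beta: float, K: float,
                  baseline: float = 0.0):
    """Evaluate the gamma-variate bolus model (continuous at t = t0)."""
    if not (alpha > 0 and beta > 0):
        raise ValidationError(f"alpha and beta must be > 0, got {alpha}, {beta}")
    t = np.asarray(t, dtype=float)
    x = t - t0
    out = np.full(t.shape, float(baseline))
    pos = x > 0
    out[pos] += K * x[pos] ** alpha * np.exp(-x[pos] / beta)
    return out if out.ndim else float(out)


def fwhm_factor(alpha: float) -> float:
    """w(alpha) such that FWHM = beta * w(alpha).

    Solves x^alpha e^(-x) = alpha^alpha e^(-alpha) / 2 on either side of
    the mode x = alpha (in log space for stability).
    """
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")

    def g(x):  # log of model / log of half-peak
        return alpha * np.log(x) - x - (alpha * np.log(alpha) - alpha - np.log(2.0))

    left = brentq(g, 1e-12, alpha, xtol=1e-12, rtol=8.9e-16)
    hi = 2.0 * alpha + 10.0
    while g(hi) > 0:
        hi *= 2.0
    right = brentq(g, alpha, hi, xtol=1e-12, rtol=8.9e-16)
    return float(right - left)


@dataclass
class GammaVariateFit:
    """Converged gamma-variate parameters with derived TTP and FWHM."""

    t0: float
    alpha: float
    beta: float
    K: float
    baseline: float
    r_squared: float
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValidationError("fit requires alpha > 0 and beta > 0")

    @property
    def ttp(self) -> float:
        """Time to peak, t0 + alpha*beta (analytic identity)."""
        return self.t0 + self.alpha * self.beta

    @property
    def fwhm(self) -> float:
        return compute_fwhm(self)

    @property
    def peak(self) -> float:
        return self.baseline + self.K * (self.alpha * self.beta) ** self.alpha \
            * np.exp(-self.alpha)

    def __call__(self, t):
        return gamma_variate(t, self.t0, self.alpha, self.beta, self.K,
                             self.baseline)

    def to_dict(self) -> dict:
        return {"t0": self.t0, "alpha": self.alpha, "beta": self.beta,
                "K": self.K, "baseline": self.baseline, "r2": self.r_squared,
                "ttp_s": self.ttp, "fwhm_s": self.fwhm}


def compute_fwhm(fit: GammaVariateFit) -> float:
    """Full width at half maximum of the fitted analytic curve.

    The half-maximum level is baseline + (peak - baseline)/2; left and
    right crossings are bracketed around the mode and solved to 1e-9 s.
    """
    ab = fit.alpha * fit.beta
    tp = fit.t0 + ab

    def f(t):
        return (t - fit.t0) ** fit.alpha * np.exp(-(t - fit.t0) / fit.beta) \
            - 0.5 * ab ** fit.alpha * np.exp(-fit.alpha)

    lo = fit.t0 + 1e-15 * max(1.0, abs(fit.t0))
    if f(lo) >= 0:
        # tiny alpha: the rise is so steep that the left crossing sits
        # below floating-point resolution of t0 — it IS the arrival time
        left = lo
    else:
        left = brentq(f, lo, tp, xtol=1e-9)
    hi = tp + 2 * ab + 10 * fit.beta
    while f(hi) > 0:
        hi += 10 * fit.beta
    right = brentq(f, tp, hi, xtol=1e-9)
    return float(right - left)


def _robust_noise(d: np.ndarray) -> float:
    """Noise s.d. from median absolute successive differences."""
    diffs = np.abs(np.diff(d))
    return float(1.4826 * np.median(diffs) / np.sqrt(2.0))


def fit_gamma_variate(tdc: TDC, min_samples: int = 8,
                      peak_snr: float = 3.0) -> GammaVariateFit:
    """Nonlinear least squares of the gamma-variate model on the TDC grid.

    Initialization scans t0 candidates in [0, argmax time); at each, alpha
    and 1/beta come from a log-linearized regression of
    log(C - baseline) on log(t - t0) and (t - t0). The best candidate
    seeds a bounded trust-region refinement with free baseline. Uniform
    weights across samples (each frame is one measurement).

    Raises :class:`FitError` for flat, monotone or too-short curves and
    warns when r^2 < 0.8.
    """
    t = tdc.grid.timestamps
    d = np.asarray(tdc.density, dtype=float)
    if d.size < min_samples:
        raise FitError(f"need >= {min_samples} samples, got {d.size}")
    base0 = float(np.median(d[:2]))
    peak_idx = int(np.argmax(d))
    noise = _robust_noise(d)
    if d[peak_idx] - base0 <= peak_snr * max(noise, 1e-300):
        raise FitError("no discernible peak above the noise floor")
    if peak_idx == 0 or peak_idx == d.size - 1:
        raise FitError("monotone TDC: peak lies on the grid boundary")

    t_peak = t[peak_idx]
    span = t[-1] - t[0]
    candidates = np.unique(np.concatenate([
        np.linspace(0.0, t_peak * 0.98, 24), t[:peak_idx]]))
    best = None
    for t0c in candidates:
        sel = (t > t0c + 1e-9) & (d - base0 > 0.02 * (d[peak_idx] - base0))
        if sel.sum() < 4:
            continue
        x = t[sel] - t0c
        y = np.log(d[sel] - base0)
        A = np.column_stack([np.ones_like(x), np.log(x), -x])
        try:
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        except np.linalg.LinAlgError:
            continue
        lnK, alpha, inv_beta = coef
        if alpha <= 0 or inv_beta <= 0 or alpha > 100:
            continue
        params = (t0c, alpha, 1.0 / inv_beta, np.exp(lnK), base0)
        resid = gamma_variate(t, *params) - d
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, params)
    if best is None:
        raise FitError("no feasible log-linear initialization found")

    p0 = np.asarray(best[1])
    lo = [-span, 1e-6, 1e-6, 1e-300, -np.inf]
    hi_b = [t_peak - 1e-6, 100.0, 10.0 * span, np.inf, np.inf]
    p0 = np.clip(p0, lo, hi_b)

    def resid_fn(p):
        t0c, alpha, beta, K, base = p
        return gamma_variate(t, t0c, alpha, beta, K, base) - d

    sol = least_squares(resid_fn, p0, bounds=(lo, hi_b), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
    t0f, alpha, beta, K, base = sol.x
    if not (alpha > 0 and beta > 0):
        raise FitError("fitted shape or scale non-positive")
    ss_res = float(sol.fun @ sol.fun)
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    warns: list[str] = []
    if r2 < 0.8:
        msg = f"poor gamma-variate fit: r^2 = {r2:.3f}"
        warns.append(msg)
        logger.warning(msg)
    return GammaVariateFit(t0=float(t0f), alpha=float(alpha), beta=float(beta),
                           K=float(K), baseline=float(base), r_squared=r2,
                           warnings_=warns)


def compute_ttp(tdc: TDC, method: str = "argmax") -> float:
    """Time at which a TDC attains its maximum.

    ``argmax`` takes the timestamp of the maximum sample (ties resolve to
    the earliest, with a warning); ``fitted`` uses t0 + alpha*beta from a
    gamma-variate fit.
    """
    d = np.asarray(tdc.density, dtype=float)
    if np.ptp(d) == 0:
        raise ValidationError("degenerate (constant) TDC")
    if method == "argmax":
        maxima = np.flatnonzero(d == d.max())
        if maxima.size > 1:
            logger.warning("TDC %s: %d tied maxima; earliest returned",
                           tdc.label, maxima.size)
        return float(tdc.grid.timestamps[maxima[0]])
    if method == "fitted":
        return fit_gamma_variate(tdc).ttp
    raise ValidationError(f"unknown TTP method {method!r}")


@dataclass
class AMTTResult:
    """Full audit trail of one automatic aMTT computation.

    ``label`` is ``"aMTT_AP"`` or ``"aMTT_Lat"``; ``amtt_s`` is None when
    the capillary fit failed (``valid`` False). All pipeline intermediates
    are retained for inspection and export.
    """

    label: str
    amtt_s: Optional[float]
    valid: bool
    fit: Optional[GammaVariateFit]
    capillary_tdc: Optional[TDC]
    components: Optional[ComponentSet]
    masks: dict[str, VesselMask] = field(default_factory=dict)
    tdcs: dict[str, TDC] = field(default_factory=dict)
    transforms: list[RigidTransform] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)
    seed: int = 0


def compute_amtt(series: DSASeries, seed: int, register: bool = True,
                 min_matches: int = 8, max_iter: int = 500, tol: float = 1e-4,
                 n_bins: int = 256) -> AMTTResult:
    """Fully automatic aMTT for one view.

    Pipeline: motion-correct to the t = 0 reference -> flatten -> 3-source
    FastICA -> sign fixing -> TTP-ordered phase labels -> Otsu capillary
    mask -> TDC from the registered series -> gamma-variate fit -> FWHM.
    ``register=False`` skips motion correction for inputs known to be
    motionless. Deterministic given the seed.
    """
    label = "aMTT_AP" if series.view == "AP" else "aMTT_Lat"
    warns: list[str] = []
    transforms: list[RigidTransform] = []
    if register:
        series, transforms = register_series(series, min_matches=min_matches)

    data, shape = flatten_series(series)
    comps = decompose(data, shape, seed=seed, max_iter=max_iter, tol=tol)
    if not comps.converged:
        warns.append("ICA did not converge within max_iter")
    comps = assign_phases(fix_signs(comps), series.grid)

    masks: dict[str, VesselMask] = {}
    tdcs: dict[str, TDC] = {}
    cap_tdc: Optional[TDC] = None
    for phase in ("arterial", "capillary", "venous"):
        vm = make_mask(comps.map_for(phase), phase, n_bins=n_bins)
        masks[phase] = vm
        if vm.degenerate:
            warns.append(f"degenerate {phase} mask")
            continue
        tdcs[phase] = extract_tdc(series, vm)
    cap_tdc = tdcs.get("capillary")

    if cap_tdc is not None and detect_two_peaks(cap_tdc.density):
        warns.append("capillary TDC shows two distinguishable peaks "
                     "(possible arterial leakage into the capillary component)")
        logger.warning(warns[-1])

    fit = None
    amtt = None
    valid = False
    if cap_tdc is not None:
        try:
            fit = fit_gamma_variate(cap_tdc)
            warns.extend(fit.warnings_)
            amtt = fit.fwhm
            valid = True
        except FitError as exc:
            warns.append(f"capillary fit failed: {exc}")
            logger.warning("capillary fit failed: %s", exc)
    else:
        warns.append("no capillary TDC could be extracted")

    return AMTTResult(label=label, amtt_s=amtt, valid=valid, fit=fit,
                      capillary_tdc=cap_tdc, components=comps, masks=masks,
                      tdcs=tdcs, transforms=transforms, warnings_=warns,
                      seed=seed)


@dataclass
class CCTResult:
    """Cerebral circulation time: TTP(parietal vein) - TTP(cavernous ICA)."""

    ttp_artery: float
    ttp_vein: float
    method: str
    warnings_: list[str] = field(default_factory=list)

    @property
    def cct(self) -> float:
        return self.ttp_vein - self.ttp_artery


ARTERY_ROI = "cavernous_ICA"
VEIN_ROI = "parietal_vein"


def compute_cct(series: DSASeries, rois: ROISet, method: str = "argmax",
                ) -> CCTResult:
    """CCT from manual ROIs on a (nominally lateral) series.

    Requires ROI labels ``"cavernous_ICA"`` and ``"parietal_vein"``. An AP
    view only warns (the landmarks are defined on the lateral projection)
    and the value is computed anyway.
    """
    for label in (ARTERY_ROI, VEIN_ROI):
        if label not in rois.regions:
            raise ValidationError(f"ROI set lacks required label {label!r}")
    warns: list[str] = []
    if series.view != "LAT":
        warns.append("CCT landmarks are defined on the lateral view; "
                     f"series view is {series.view}")
        logger.warning(warns[-1])

    ttps = {}
    for label in (ARTERY_ROI, VEIN_ROI):
        vm = VesselMask(mask=rois.regions[label], phase=label, threshold=0.0,
                        fraction_on=float(rois.regions[label].mean()))
        ttps[label] = compute_ttp(extract_tdc(series, vm), method=method)
    res = CCTResult(ttp_artery=ttps[ARTERY_ROI], ttp_vein=ttps[VEIN_ROI],
                    method=method, warnings_=warns)
    if res.cct < 0:
        res.warnings_.append(f"negative CCT ({res.cct:.2f} s)")
        logger.warning("negative CCT (%.2f s)", res.cct)
    return res


def correlate_markers(table, min_cases: int = 3):
    """Pairwise Pearson correlations between per-case marker columns.

    ``table`` is a pandas DataFrame (cases x markers). Returns a DataFrame
    with one row per unordered pair: r, two-sided p, n, and a significance
    flag at p < 0.05 (raw, uncorrected). Pairs with fewer than
    ``min_cases`` complete cases or a zero-variance column are reported
    with missing r/p.
    """
    import pandas as pd

    cols = list(table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            if n < min_cases or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                rows.append({"x": a, "y": b, "r": np.nan, "p": np.nan,
                             "n": n, "significant": False})
                continue
            r, p = pearsonr(sub[a], sub[b])
            rows.append({"x": a, "y": b, "r": float(r), "p": float(p),
                         "n": n, "significant": bool(p < 0.05)})
    return pd.DataFrame(rows)
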