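"""Core data model and I/O for dynamic DSA series.

Defines the acquisition schedule / time-grid machinery, the canonical
in-memory series container (:class:`DSASeries`), manual ROI sets, and the
marker report with its JSON/CSV writers.

Density convention
------------------
Canonical frames hold *positive contrast density*: larger value means more
iodinated contrast, and the reference frame at t = 0 is approximately zero
everywhere. Subtraction angiograms conventionally render contrast dark, so
readers accept an ``invert`` flag.
"""

from __future__ import annotations

import base64
import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "TimeGrid",
    "DSASeries",
    "ROISet",
    "MarkerReport",
    "ValidationError",
    "build_time_grid",
    "read_series",
    "write_series",
    "write_report",
    "read_report",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Multi-rate frame acquisition schedule.

    Parameters
    ----------
    segments
        Ordered ``(frame_rate_fps, duration_s)`` pairs. Each segment is
        half-open ``[start, start + duration)``: a frame lands exactly on a
        segment start, never on its end, so rate x duration need not be an
        integer.
    extension_rate, extension_duration
        Optional prolongation appended after the base segments (used
        clinically to visualize slow venous outflow).
    """

    segments: tuple[tuple[float, float], ...]
    extension_rate: float = 2.0
    extension_duration: float = 0.0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValidationError("schedule needs at least one segment")
        object.__setattr__(self, "segments", tuple((float(r), float(d)) for r, d in self.segments))
        for rate, dur in self.segments:
            if not (rate > 0 and np.isfinite(rate)):
                raise ValidationError(f"non-positive frame rate: {rate}")
            if not (dur > 0 and np.isfinite(dur)):
                raise ValidationError(f"non-positive segment duration: {dur}")
        if self.extension_rate <= 0:
            raise ValidationError("extension_rate must be > 0")
        if self.extension_duration < 0:
            raise ValidationError("extension_duration must be >= 0")

    @property
    def base_duration(self) -> float:
        """Total duration of the base segments, seconds."""
        return float(sum(d for _, d in self.segments))

    @property
    def total_duration(self) -> float:
        return self.base_duration + float(self.extension_duration)

    @classmethod
    def default(cls, extension_duration: float = 0.0) -> "AcquisitionSchedule":
        """The clinical biplane protocol: 7.5 fps for 5 s, 4 fps for 3 s,
        3 fps for 2 s, 2 fps for 2 s — a 12-second base acquisition."""
        return cls(segments=((7.5, 5.0), (4.0, 3.0), (3.0, 2.0), (2.0, 2.0)),
                   extension_rate=2.0, extension_duration=extension_duration)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing frame timestamps in seconds, starting at 0."""

    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1 or ts.size < 2:
            raise ValidationError("time grid needs >= 2 timestamps")
        if not np.all(np.isfinite(ts)):
            raise ValidationError("non-finite timestamp")
        if ts[0] != 0.0:
            raise ValidationError("first timestamp must be 0")
        if np.any(np.diff(ts) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def local_interval(self, t: float) -> float:
        """Frame spacing local to time ``t`` (spacing of the enclosing pair)."""
        ts = self.timestamps
        i = int(np.clip(np.searchsorted(ts, t), 1, ts.size - 1))
        return float(ts[i] - ts[i - 1])


def build_time_grid(schedule: AcquisitionSchedule) -> TimeGrid:
    """Place frames on the cumulative time axis of a multi-rate schedule.

    Within each half-open segment ``[start, start + duration)`` frames are
    spaced ``1 / frame_rate`` apart starting at the segment start; the first
    frame of the acquisition is at t = 0.
    """
    times: list[np.ndarray] = []
    start = 0.0
    segs = list(schedule.segments)
    if schedule.extension_duration > 0:
        segs.append((schedule.extension_rate, schedule.extension_duration))
    for rate, dur in segs:
        n = int(np.ceil(rate * dur - 1e-9))  # frames strictly inside [start, start+dur)
        times.append(start + np.arange(n) / rate)
        start += dur
    return TimeGrid(np.concatenate(times))


@dataclass
class DSASeries:
    """A time-ordered stack of subtraction frames with a non-uniform grid.

    ``frames`` is ``(T, H, W)`` float contrast density; ``grid`` has T
    entries; ``view`` is ``"AP"`` or ``"LAT"``.
    """

    frames: np.ndarray
    grid: TimeGrid
    view: str = "AP"
    polarity_note: str = "canonical"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValidationError(f"frames must be (T, H, W), got shape {f.shape}")
        if f.shape[0] != len(self.grid):
            raise ValidationError(
                f"frame count {f.shape[0]} != grid length {len(self.grid)}")
        if f.shape[1] < 16 or f.shape[2] < 16:
            raise ValidationError("frames must be at least 16x16")
        if not np.all(np.isfinite(f)):
            raise ValidationError("non-finite pixel value")
        if self.view not in ("AP", "LAT"):
            raise ValidationError(f"view must be 'AP' or 'LAT', got {self.view!r}")
        self.frames = f

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ROISet:
    """Named regions of interest: polygons (pixel (x, y) vertices) or masks.

    Polygons are rasterized with an even-odd fill rule, vertices inclusive.
    """

    regions: dict[str, np.ndarray]  # name -> boolean H x W mask
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        seen = set()
        for name, mask in self.regions.items():
            if name in seen:
                raise ValidationError(f"duplicate ROI label {name!r}")
            seen.add(name)
            m = np.asarray(mask, dtype=bool)
            if m.shape != tuple(self.shape):
                raise ValidationError(
                    f"ROI {name!r} mask shape {m.shape} != frame shape {self.shape}")
            if not m.any():
                raise ValidationError(f"ROI {name!r} is empty")
            self.regions[name] = m

    @classmethod
    def from_polygons(cls, polygons: dict[str, Sequence[Sequence[float]]],
                      shape: tuple[int, int]) -> "ROISet":
        """Rasterize named ``[(x, y), ...]`` polygons onto an H x W canvas."""
        from matplotlib.path import Path as MplPath

        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        regions = {}
        for name, poly in polygons.items():
            verts = np.asarray(poly, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise ValidationError(f"ROI {name!r}: polygon needs >= 3 (x, y) vertices")
            if (verts[:, 0].min() < -0.5 or verts[:, 0].max() > w - 0.5
                    or verts[:, 1].min() < -0.5 or verts[:, 1].max() > h - 0.5):
                raise ValidationError(f"ROI {name!r} extends outside frame bounds")
            path = MplPath(verts)
            # radius>0 makes boundary vertices inclusive
            mask = path.contains_points(pts, radius=1e-9).reshape(h, w)
            regions[name] = mask
        return cls(regions=regions, shape=(h, w))

    @classmethod
    def from_json(cls, path: str | Path, shape: tuple[int, int]) -> "ROISet":
        """Load ROIs from JSON: named polygons or base64-encoded masks."""
        doc = json.loads(Path(path).read_text())
        polygons: dict[str, list] = {}
        masks: dict[str, np.ndarray] = {}
        for name, spec in doc.items():
            if isinstance(spec, dict) and "mask_base64" in spec:
                raw = base64.b64decode(spec["mask_base64"])
                m = np.frombuffer(raw, dtype=np.uint8)
                masks[name] = (m.reshape(shape) > 0)
            else:
                polygons[name] = spec["polygon"] if isinstance(spec, dict) else spec
        out = cls.from_polygons(polygons, shape) if polygons else cls({}, shape)
        out.regions.update(
            cls(regions=masks, shape=shape).regions if masks else {})
        if not out.regions:
            raise ValidationError("ROI file defines no regions")
        return out


@dataclass
class MarkerReport:
    """Aggregated hemodynamic markers for one case.

    ``amtt_s`` maps ``"aMTT_AP"`` / ``"aMTT_Lat"`` to seconds (or None when
    a view was not analyzed or its capillary fit failed); ``cct_s`` is the
    manual-ROI cerebral circulation time (None without ROIs). ``fits`` holds
    per-view gamma-variate parameter dicts, ``tdcs`` per-label
    ``(timestamps, density)`` pairs for CSV export, and ``provenance``
    records inputs, seed, version and parameters.
    """

    amtt_s: dict[str, Optional[float]] = field(default_factory=dict)
    cct_s: Optional[float] = None
    fits: dict[str, dict] = field(default_factory=dict)
    tdcs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.amtt_s.items():
            if val is not None and not (np.isfinite(val) and val >= 0):
                raise ValidationError(f"{key} must be finite and >= 0, got {val}")
        if self.cct_s is not None and not np.isfinite(self.cct_s):
            raise ValidationError("cct_s must be finite")


def _read_dicom(path: Path, timestamps: Optional[TimeGrid]) -> tuple[np.ndarray, TimeGrid]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if timestamps is None:
        ftv = getattr(ds, "FrameTimeVector", None)
        if ftv is not None:
            inc = np.asarray([float(v) for v in ftv]) / 1000.0  # ms -> s
            ts = np.cumsum(inc) - inc[0]
            timestamps = TimeGrid(ts)
        elif getattr(ds, "FrameTime", None) is not None:
            dt = float(ds.FrameTime) / 1000.0
            timestamps = TimeGrid(np.arange(arr.shape[0]) * dt)
        else:
            raise ValidationError(
                "DICOM carries no frame-time vector; pass timestamps explicitly")
    return arr, timestamps


def read_series(path: str | Path, timestamps: Optional[TimeGrid] = None,
                view: str = "AP", invert: bool = False,
                subtract_baseline: bool = True) -> DSASeries:
    """Read a frame stack (DICOM multiframe, multi-page TIFF, or NPY).

    ``timestamps`` is required when the container carries no frame-time
    vector (TIFF and NPY always require it; a sibling ``*.timestamps.json``
    with ``{"timestamps_s": [...]}`` is picked up automatically).
    ``invert`` flips polarity for sources that encode contrast as darker
    pixels; ``subtract_baseline`` subtracts frame 0 so the reference frame
    is exactly zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()

    if timestamps is None:
        sidecar = path.with_suffix(path.suffix + ".timestamps.json")
        alt = path.with_suffix(".timestamps.json")
        for cand in (sidecar, alt):
            if cand.exists():
                doc = json.loads(cand.read_text())
                timestamps = TimeGrid(np.asarray(doc["timestamps_s"], dtype=float))
                break

    if suffix in (".dcm", ".dicom"):
        arr, timestamps = _read_dicom(path, timestamps)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)), dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    elif suffix == ".npy":
        arr = np.asarray(np.load(str(path)), dtype=float)
    else:
        raise ValidationError(f"unsupported container {suffix!r}")

    if timestamps is None:
        raise ValidationError("no timestamps available; pass a TimeGrid")
    if arr.shape[0] != len(timestamps):
        raise ValidationError(
            f"frame count {arr.shape[0]} != timestamp count {len(timestamps)}")

    polarity = "canonical"
    if invert:
        arr = arr.max() - arr
        polarity = "inverted-on-load"
    if subtract_baseline:
        arr = arr - arr[0]
    return DSASeries(frames=arr, grid=timestamps, view=view, polarity_note=polarity)


def write_series(series: DSASeries, path: str | Path) -> None:
    """Write an NPY stack plus a ``*.timestamps.json`` sidecar."""
    path = Path(path)
    np.save(str(path), series.frames)
    actual = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = actual.with_suffix(".timestamps.json")
    sidecar.write_text(json.dumps(
        {"timestamps_s": series.grid.timestamps.tolist(), "view": series.view}))


def write_report(report: MarkerReport, path: str | Path) -> None:
    """Write the report JSON; TDC CSVs (``t_s,density``) go alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "aMTT_AP": report.amtt_s.get("aMTT_AP"),
        "aMTT_Lat": report.amtt_s.get("aMTT_Lat"),
        "cct_s": report.cct_s,
        "fits": report.fits,
        "warnings": report.warnings,
        "provenance": report.provenance,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    for label, (ts, dens) in report.tdcs.items():
        csv_path = path.parent / f"tdc_{label}.csv"
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t_s", "density"])
            for t, d in zip(ts, dens):
                writer.writerow([repr(float(t)), repr(float(d))])


def read_report(path: str | Path) -> MarkerReport:
    doc = json.loads(Path(path).read_text())
    amtt = {k: doc.get(k) for k in ("aMTT_AP", "aMTT_Lat")}
    tdcs = {}
    for csv_path in Path(path).parent.glob("tdc_*.csv"):
        label = csv_path.stem[len("tdc_"):]
        rows = list(csv.reader(open(csv_path)))[1:]
        ts = np.asarray([float(r[0]) for r in rows])
        dens = np.asarray([float(r[1]) for r in rows])
        tdcs[label] = (ts, dens)
    return MarkerReport(amtt_s=amtt, cct_s=doc.get("cct_s"),
                        fits=doc.get("fits", {}), tdcs=tdcs,
                        warnings=doc.get("warnings", []),
                        provenance=doc.get("provenance", {}))
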