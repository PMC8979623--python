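"""Waveform re-digitization from screen-capture images.

Clinical hemodynamic and echo systems display waveforms the operator can
only export as raster screenshots: a pulmonary-artery pressure trace with
an ECG strip, or a pulsed-wave Doppler spectrogram with an ECG strip.
This module recovers calibrated physical time series from such captures:

1. :func:`load_capture` loads a PNG/JPEG as normalized grayscale.
2. :func:`detect_line_trace` / :func:`detect_doppler_envelope` scan a
   rectangular region column by column and return one fractional pixel
   row per column (the trace path, or the outer velocity envelope).
3. :func:`fill_gaps` interpolates occluded columns (cursors, annotations).
4. :func:`calibrate_trace` maps pixels to seconds and physical units via
   two user-supplied anchors per axis.
5. :func:`resample_uniform` linearly resamples onto a uniform grid
   (1000 Hz by default).

Pixel conventions: coordinates are 0-based, rectangles are half-open
``[left, right) x [top, bottom)``, and rows increase downward; the signed
y-axis affine map absorbs the downward orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigError, DataError, DetectionError, InputError

__all__ = [
    "CaptureImage",
    "RegionSpec",
    "AxisCalibration",
    "RawTrace",
    "TimeSeries",
    "CalibratedSignal",
    "load_capture",
    "detect_line_trace",
    "detect_doppler_envelope",
    "fill_gaps",
    "calibrate_trace",
    "resample_uniform",
    "DEFAULT_THRESHOLD",
    "DEFAULT_RATE_HZ",
]

#: Default detection threshold on normalized intensity: traces are drawn
#: near-white on near-black on clinical displays.
DEFAULT_THRESHOLD = 0.5

#: Resampling rate applied to every digitized waveform.
DEFAULT_RATE_HZ = 1000.0

# Rec. 709 luminance weights used for color -> grayscale conversion.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class CaptureImage:
    """A screen capture as a normalized grayscale pixel grid."""

    pixels: np.ndarray  # (height, width) float in [0, 1]
    source_path: str
    capture_kind: str  # "pressure" | "doppler" | "ecg-only"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise InputError(f"capture must be a 2-D image of at least 2x2 pixels, got shape {px.shape}")
        if np.nanmin(px) < 0.0 or np.nanmax(px) > 1.0:
            raise InputError("capture intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular region of interest containing exactly one trace.

    ``baseline_row`` (zero-velocity line) and ``envelope_direction`` are
    meaningful only for ``trace_kind == "doppler_envelope"``.
    """

    left: int
    top: int
    right: int
    bottom: int
    trace_kind: str = "line_trace"  # "line_trace" | "doppler_envelope" | "ecg"
    envelope_direction: str = "above_baseline"  # or "below_baseline"
    baseline_row: int | None = None

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise ConfigError(
                f"region rectangle is empty: [{self.left},{self.right}) x [{self.top},{self.bottom})"
            )
        if self.trace_kind not in ("line_trace", "doppler_envelope", "ecg"):
            raise ConfigError(f"unknown trace_kind {self.trace_kind!r}")
        if self.envelope_direction not in ("above_baseline", "below_baseline"):
            raise ConfigError(f"unknown envelope_direction {self.envelope_direction!r}")
        if self.trace_kind == "doppler_envelope":
            if self.baseline_row is None:
                raise ConfigError("doppler_envelope region requires baseline_row")
            if not (self.top <= self.baseline_row < self.bottom):
                raise ConfigError("baseline_row must lie inside the region")

    def validate_inside(self, image: CaptureImage) -> None:
        if self.left < 0 or self.top < 0 or self.right > image.width or self.bottom > image.height:
            raise ConfigError(
                f"region [{self.left},{self.right}) x [{self.top},{self.bottom}) exceeds "
                f"image {image.width}x{image.height}"
            )


@dataclass(frozen=True)
class AxisCalibration:
    """Affine pixel -> physical mapping from two anchors per axis.

    ``x_anchors`` maps pixel columns to time in seconds, ``y_anchors``
    maps pixel rows to the physical value in ``unit``.  The y slope is
    normally negative (rows grow downward while values grow upward).
    """

    x_anchors: tuple[tuple[float, float], tuple[float, float]]
    y_anchors: tuple[tuple[float, float], tuple[float, float]]
    unit: str

    def __post_init__(self) -> None:
        (xp0, xt0), (xp1, xt1) = self.x_anchors
        (yp0, yv0), (yp1, yv1) = self.y_anchors
        if xp0 == xp1:
            raise ConfigError("x-axis anchors share the same pixel column (non-invertible)")
        if yp0 == yp1:
            raise ConfigError("y-axis anchors share the same pixel row (non-invertible)")
        if (xt1 - xt0) / (xp1 - xp0) <= 0:
            raise ConfigError("time must increase with pixel column (positive time scale)")
        if yv0 == yv1:
            raise ConfigError("y-axis anchors share the same value (zero y-scale)")

    # -- forward maps ------------------------------------------------------
    def col_to_time(self, col):
        (xp0, xt0), (xp1, xt1) = self.x_anchors
        return xt0 + (np.asarray(col, dtype=float) - xp0) * (xt1 - xt0) / (xp1 - xp0)

    def row_to_value(self, row):
        (yp0, yv0), (yp1, yv1) = self.y_anchors
        return yv0 + (np.asarray(row, dtype=float) - yp0) * (yv1 - yv0) / (yp1 - yp0)

    # -- inverse maps (used by the renderer and round-trip tests) ----------
    def time_to_col(self, t):
        (xp0, xt0), (xp1, xt1) = self.x_anchors
        return xp0 + (np.asarray(t, dtype=float) - xt0) * (xp1 - xp0) / (xt1 - xt0)

    def value_to_row(self, v):
        (yp0, yv0), (yp1, yv1) = self.y_anchors
        return yp0 + (np.asarray(v, dtype=float) - yv0) * (yp1 - yp0) / (yv1 - yv0)

    @property
    def seconds_per_px(self) -> float:
        (xp0, xt0), (xp1, xt1) = self.x_anchors
        return (xt1 - xt0) / (xp1 - xp0)

    @property
    def units_per_px(self) -> float:
        (yp0, yv0), (yp1, yv1) = self.y_anchors
        return (yv1 - yv0) / (yp1 - yp0)


@dataclass(frozen=True)
class RawTrace:
    """Column-wise trace path in pixel space; NaN rows mark missing columns."""

    columns: np.ndarray  # strictly increasing int columns
    rows: np.ndarray  # fractional rows, NaN = not detected

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=int)
        rows = np.asarray(self.rows, dtype=float)
        if cols.shape != rows.shape or cols.ndim != 1:
            raise DataError("trace columns and rows must be 1-D and equal length")
        if cols.size >= 2 and not np.all(np.diff(cols) > 0):
            raise DataError("trace columns must be strictly increasing")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "rows", rows)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.rows).sum())


@dataclass(frozen=True)
class TimeSeries:
    """Calibrated but not-yet-uniform samples (one per detected pixel column)."""

    times: np.ndarray  # s, strictly increasing
    values: np.ndarray
    unit: str
    label: str = ""


@dataclass(frozen=True)
class CalibratedSignal:
    """Uniformly sampled physical time series."""

    t0: float
    rate: float  # Hz
    values: np.ndarray
    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise DataError("sample rate must be positive")
        if vals.size < 2:
            raise DataError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise DataError("signal values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate

    def scaled(self, factor: float, unit: str | None = None, label: str | None = None) -> "CalibratedSignal":
        return replace(
            self,
            values=self.values * factor,
            unit=self.unit if unit is None else unit,
            label=self.label if label is None else label,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_capture(path: str | Path, kind: str = "pressure") -> CaptureImage:
    """Load a PNG/JPEG capture as grayscale intensities in [0, 1].

    Color images are converted with Rec. 709 luminance weights
    (0.2126 R + 0.7152 G + 0.0722 B).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"capture image not found: {p}")
    try:
        with Image.open(p) as im:
            im.load()
            if im.mode in ("L", "I", "I;16", "F"):
                px = np.asarray(im.convert("F"), dtype=float)
                if px.size and px.max() > 1.0:
                    px = px / 255.0
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=float) / 255.0
                px = rgb @ _LUMA
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise InputError(f"cannot decode capture image {p}: {exc}") from exc
    return CaptureImage(pixels=np.clip(px, 0.0, 1.0), source_path=str(p), capture_kind=kind)


def _region_pixels(image: CaptureImage, region: RegionSpec) -> np.ndarray:
    region.validate_inside(image)
    return image.pixels[region.top:region.bottom, region.left:region.right]


def _fail_if_sparse(rows: np.ndarray, region: RegionSpec) -> None:
    missing = np.isnan(rows).mean()
    if missing > 0.5:
        raise DetectionError(
            f"trace not found in region [{region.left},{region.right})x[{region.top},{region.bottom}): "
            f"{missing:.0%} of columns have no pixel above threshold"
        )


def detect_line_trace(
    image: CaptureImage, region: RegionSpec, threshold: float = DEFAULT_THRESHOLD
) -> RawTrace:
    """Column-wise sub-pixel path of a bright line trace.

    For each pixel column in the region, returns the intensity-weighted
    centroid row of the pixels at or above ``threshold``.  Columns with no
    super-threshold pixel are marked missing; more than 50% missing is a
    detection failure.
    """
    if region.trace_kind not in ("line_trace", "ecg"):
        raise ConfigError("detect_line_trace requires a line_trace or ecg region")
    sub = _region_pixels(image, region)
    mask = sub >= threshold
    weights = np.where(mask, sub, 0.0)
    wsum = weights.sum(axis=0)
    row_idx = np.arange(region.top, region.bottom, dtype=float)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        rows = (weights * row_idx).sum(axis=0) / wsum
    rows[wsum == 0.0] = np.nan
    _fail_if_sparse(rows, region)
    cols = np.arange(region.left, region.right)
    return RawTrace(columns=cols, rows=rows)


def _nan_median_smooth(rows: np.ndarray, window: int) -> np.ndarray:
    """Running median ignoring NaNs; missing columns stay missing.

    Near the array edges the window shrinks symmetrically (5 -> 3 -> 1):
    an asymmetric window would bias steep monotone segments by up to a
    column's worth of slope, while a symmetric one preserves them.
    """
    half = window // 2
    out = np.full_like(rows, np.nan)
    n = rows.size
    for i in range(n):
        if np.isnan(rows[i]):
            continue
        h = min(half, i, n - 1 - i)
        w = rows[i - h: i + h + 1]
        out[i] = np.nanmedian(w)
    return out


def detect_doppler_envelope(
    image: CaptureImage,
    region: RegionSpec,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_window: int = 5,
) -> RawTrace:
    """Outer velocity envelope of a Doppler spectrogram region.

    Per column, the outermost super-threshold pixel row — the one farthest
    from ``baseline_row`` in ``envelope_direction`` — is taken as the
    maximum-velocity edge, then median-smoothed across ``smooth_window``
    columns to suppress single-column speckle.
    """
    if region.trace_kind != "doppler_envelope":
        raise ConfigError("detect_doppler_envelope requires a doppler_envelope region")
    sub = _region_pixels(image, region)
    mask = sub >= threshold
    row_idx = np.arange(region.top, region.bottom)
    rows = np.full(sub.shape[1], np.nan)
    if region.envelope_direction == "above_baseline":
        # farthest above the baseline = smallest row index
        ok = mask & (row_idx[:, None] <= region.baseline_row)
        any_col = ok.any(axis=0)
        first = ok.argmax(axis=0)
        rows[any_col] = row_idx[first[any_col]]
    else:
        ok = mask & (row_idx[:, None] >= region.baseline_row)
        any_col = ok.any(axis=0)
        last = ok.shape[0] - 1 - ok[::-1, :].argmax(axis=0)
        rows[any_col] = row_idx[last[any_col]]
    rows = _nan_median_smooth(rows, smooth_window)
    _fail_if_sparse(rows, region)
    cols = np.arange(region.left, region.right)
    return RawTrace(columns=cols, rows=rows)


def fill_gaps(trace: RawTrace) -> RawTrace:
    """Interpolate interior missing columns; trim missing edges.

    Interior gaps (occluding cursors, annotations) are filled by linear
    interpolation between the nearest detected neighbors.  Leading and
    trailing missing columns are dropped rather than extrapolated.
    """
    rows = trace.rows
    valid = ~np.isnan(rows)
    if valid.sum() < 2:
        raise DetectionError("fewer than 2 detected columns: cannot reconstruct trace")
    idx = np.flatnonzero(valid)
    lo, hi = idx[0], idx[-1]
    cols = trace.columns[lo:hi + 1]
    seg = rows[lo:hi + 1]
    seg_valid = ~np.isnan(seg)
    filled = np.interp(cols.astype(float), cols[seg_valid].astype(float), seg[seg_valid])
    return RawTrace(columns=cols, rows=filled)


def calibrate_trace(trace: RawTrace, cal: AxisCalibration, label: str = "") -> TimeSeries:
    """Map a gap-free pixel trace to physical (time, value) samples."""
    if np.isnan(trace.rows).any():
        raise DataError("calibrate_trace requires a gap-free trace (run fill_gaps first)")
    times = cal.col_to_time(trace.columns)
    values = cal.row_to_value(trace.rows)
    return TimeSeries(times=np.asarray(times), values=np.asarray(values), unit=cal.unit, label=label)


def resample_uniform(signal: TimeSeries, rate: float = DEFAULT_RATE_HZ) -> CalibratedSignal:
    """Linearly resample onto a uniform grid at ``rate`` spanning the input.

    Linear interpolation introduces no overshoot, which matters for
    physiologic extrema (systolic/diastolic pressures, peak velocity).
    """
    t = np.asarray(signal.times, dtype=float)
    v = np.asarray(signal.values, dtype=float)
    if t.size < 2:
        raise DataError("need at least 2 samples to resample")
    if not np.all(np.diff(t) > 0):
        raise DataError("sample times must be strictly increasing")
    if rate <= 0:
        raise DataError("resampling rate must be positive")
    n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate
    out = np.interp(grid, t, v)
    return CalibratedSignal(t0=float(t[0]), rate=float(rate), values=out, unit=signal.unit, label=signal.label)
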