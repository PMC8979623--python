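"""Synthetic hemodynamics and screen-capture rendering.

Ground truth for every stage of the pipeline comes from a three-element
Windkessel: a characteristic resistance Rc in series with the parallel
combination of a peripheral resistance Rp and a compliance C.  Its input
impedance has the closed form

    Z(f) = Rc + Rp / (1 + i * 2*pi*f * Rp * C),

so Z(0) = Rc + Rp (the total resistance) and |Z| -> Rc at high frequency
(the characteristic-impedance plateau).  Flow is a parametric half-sine
ejection pulse; pressure is synthesized per-harmonic by multiplying each
flow harmonic by Z at that harmonic's true frequency, which makes the
pressure-flow pair exactly consistent with the analytic impedance and
leaves no integrator truncation error in the oracle.

The renderer turns these signals (plus a synthetic ECG) into images that
mimic clinical screen captures — bright traces on a dark background with
dim gridlines, and a filled, speckled band for the Doppler spectrogram —
while recording the exact pixel path, calibration anchors and R-peak
times so tests can score every detection stage against truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import line_aa

from .digitizer import AxisCalibration, CalibratedSignal, RegionSpec
from .errors import InputError, RenderError

__all__ = [
    "WindkesselParams",
    "FlowPulseParams",
    "RenderStyle",
    "CaptureTruth",
    "FixtureSession",
    "simulate_flow",
    "analytic_impedance",
    "apply_windkessel",
    "simulate_ecg",
    "render_capture",
    "make_fixture_session",
    "random_fixture_params",
    "PHYSIOLOGIC_RANGES",
]

#: Parameter ranges treated as physiologic when drawing random fixtures.
PHYSIOLOGIC_RANGES = {
    "heart_rate": (50.0, 110.0),  # bpm
    "stroke_volume": (40.0, 100.0),  # mL
    "Rc": (0.02, 0.08),  # mmHg*s/mL
    "Rp": (0.2, 1.2),  # mmHg*s/mL
    "C": (1.0, 6.0),  # mL/mmHg
}


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: Rc + (Rp || C)."""

    Rc: float  # mmHg*s/mL, characteristic (proximal) resistance
    Rp: float  # mmHg*s/mL, peripheral resistance
    C: float  # mL/mmHg, total arterial compliance

    def __post_init__(self) -> None:
        if not (self.Rc > 0 and self.Rp > 0 and self.C > 0):
            raise InputError("Windkessel parameters must all be positive")
        if not self.Rc < self.Rp:
            raise InputError("physiologic ordering requires Rc < Rp")


@dataclass(frozen=True)
class FlowPulseParams:
    """Half-sine ejection pulse train parameters."""

    heart_rate: float  # bpm
    stroke_volume: float  # mL per beat
    ejection_fraction_of_cycle: float = 0.35
    hr_jitter: float = 0.0  # fractional beat-to-beat R-R variability

    def __post_init__(self) -> None:
        if not (30.0 <= self.heart_rate <= 200.0):
            raise InputError("heart_rate must lie in [30, 200] bpm")
        if not self.stroke_volume > 0:
            raise InputError("stroke_volume must be positive")
        if not (0.1 < self.ejection_fraction_of_cycle < 0.6):
            raise InputError("ejection fraction of cycle must lie in (0.1, 0.6)")
        if not (0.0 <= self.hr_jitter < 0.5):
            raise InputError("hr_jitter must lie in [0, 0.5)")


def simulate_flow(
    pulse: FlowPulseParams,
    duration: float,
    seed: int | None = 0,
    rate: float = 1000.0,
) -> tuple[CalibratedSignal, np.ndarray]:
    """Pulsatile PA flow: one half-sine ejection per beat, zero in diastole.

    Beat-to-beat R-R intervals are jittered multiplicatively with the
    given seed; each beat's samples are scaled so the discrete integral
    (sum x dt) equals ``stroke_volume`` exactly.  Returns the flow signal
    (mL/s) and the true R times (beat onsets, s).
    """
    base_rr = 60.0 / pulse.heart_rate
    if duration < 3 * base_rr:
        raise InputError("duration must cover at least 3 beats")
    rng = np.random.default_rng(seed)
    # Beat boundaries in samples.  Each beat is a whole number of samples and
    # the record ends exactly at a beat boundary, so the no-jitter record is
    # strictly periodic on the sample grid (the fixture's exactness hinges on
    # this: frequency-domain pressure synthesis then has no wrap artifact).
    max_samples = int(round(duration * rate))
    bounds = [0]
    while True:
        rr = base_rr
        if pulse.hr_jitter:
            rr *= 1.0 + pulse.hr_jitter * float(rng.standard_normal())
            rr = max(0.5 * base_rr, min(1.5 * base_rr, rr))
        nxt = bounds[-1] + int(round(rr * rate))
        if nxt > max_samples:
            break
        bounds.append(nxt)
    if len(bounds) < 4:
        raise InputError("duration must cover at least 3 complete beats")
    n_total = bounds[-1]
    q = np.zeros(n_total)
    dt = 1.0 / rate
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        rr_len = i1 - i0
        n_ej = max(2, int(round(pulse.ejection_fraction_of_cycle * rr_len)))
        tau = np.arange(n_ej) / n_ej
        shape = np.sin(np.pi * tau)
        shape *= pulse.stroke_volume / (shape.sum() * dt)  # exact discrete integral
        q[i0:i0 + n_ej] = shape
    r_times = np.asarray(bounds) / rate
    signal = CalibratedSignal(t0=0.0, rate=rate, values=q, unit="mL/s", label="PA flow")
    return signal, r_times


def analytic_impedance(wk: WindkesselParams, freq: float | np.ndarray) -> complex | np.ndarray:
    """Closed-form input impedance Z(f) of the three-element Windkessel."""
    f = np.asarray(freq, dtype=float)
    z = wk.Rc + wk.Rp / (1.0 + 1j * 2.0 * np.pi * f * wk.Rp * wk.C)
    return complex(z) if np.isscalar(freq) else z


def apply_windkessel(flow: CalibratedSignal, wk: WindkesselParams) -> CalibratedSignal:
    """Synthesize the pressure the Windkessel develops for a given flow.

    Works per-harmonic: the flow record is decomposed over its full span,
    each harmonic multiplied by Z at that harmonic's true frequency, and
    the result reconstructed — exact in the band-limited sense.
    """
    q = np.asarray(flow.values, dtype=float)
    spectrum = np.fft.rfft(q)
    freqs = np.fft.rfftfreq(q.size, d=1.0 / flow.rate)
    z = analytic_impedance(wk, freqs)
    p = np.fft.irfft(spectrum * z, n=q.size)
    return CalibratedSignal(t0=flow.t0, rate=flow.rate, values=p, unit="mmHg", label="PA pressure")


#: Gaussian R-spike width: 20 ms full width at half maximum.
_R_SIGMA = 0.020 / 2.3548


def simulate_ecg(
    heart_rate: float,
    duration: float,
    r_times: np.ndarray | None = None,
    rate: float = 1000.0,
    baseline_amplitude: float = 0.05,
) -> tuple[CalibratedSignal, np.ndarray]:
    """Synthetic ECG: unit-amplitude Gaussian R spikes over a small baseline.

    Spikes are placed at ``r_times`` when given, else every 60/heart_rate
    seconds starting at half an R-R interval.  The baseline is a slow
    low-amplitude wander (never above 0.1).  Returns the signal and the
    true R times.
    """
    if duration <= 2.0 * 60.0 / heart_rate:
        raise InputError("ECG duration must exceed two cardiac cycles")
    if baseline_amplitude > 0.1:
        raise InputError("baseline amplitude must stay at or below 0.1")
    rr = 60.0 / heart_rate
    if r_times is None:
        r_times = np.arange(rr / 2.0, duration, rr)
    r_times = np.asarray(r_times, dtype=float)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    x = baseline_amplitude * np.sin(2.0 * np.pi * 0.7 * t)
    for tr in r_times:
        x += np.exp(-0.5 * ((t - tr) / _R_SIGMA) ** 2)
    signal = CalibratedSignal(t0=0.0, rate=rate, values=x, unit="a.u.", label="ECG")
    return signal, r_times


@dataclass(frozen=True)
class RenderStyle:
    """Layout and appearance of a synthetic screen capture."""

    px_per_second: float = 200.0
    height_px: int = 480
    waveform_top: int = 20
    waveform_bottom: int = 360
    ecg_top: int = 380
    ecg_bottom: int = 460
    background: float = 0.05
    trace_intensity: float = 1.0
    grid_intensity: float = 0.2
    grid_spacing_px: int = 50
    band_intensity: float = 0.9
    speckle_density: float = 0.0  # dropout fraction inside the Doppler band
    salt_density: float = 0.0  # bright speckle outside the band (off by default)
    noise_sigma: float = 0.0  # additive Gaussian background noise
    value_margin: float = 0.10  # head-room fraction above/below the waveform

    def __post_init__(self) -> None:
        if self.px_per_second <= 0:
            raise InputError("px_per_second must be positive")
        if not (0 <= self.waveform_top < self.waveform_bottom <= self.ecg_top < self.ecg_bottom <= self.height_px):
            raise InputError("render regions must be stacked inside the image height")


@dataclass(frozen=True)
class CaptureTruth:
    """Everything the renderer knows exactly, for scoring detections."""

    waveform_region: RegionSpec
    ecg_region: RegionSpec
    waveform_cal: AxisCalibration
    ecg_cal: AxisCalibration
    true_path_rows: np.ndarray  # waveform row per column (fractional)
    ecg_path_rows: np.ndarray
    r_times: np.ndarray | None


def _affine_cal(col0: float, t0: float, pps: float, row_top: int, v_top: float,
                row_bot: int, v_bot: float, unit: str) -> AxisCalibration:
    return AxisCalibration(
        x_anchors=((col0, t0), (col0 + pps, t0 + 1.0)),
        y_anchors=((float(row_top), v_top), (float(row_bot), v_bot)),
        unit=unit,
    )


def _draw_polyline(img: np.ndarray, cols: np.ndarray, rows: np.ndarray, intensity: float) -> None:
    r = np.round(rows).astype(int)
    c = cols.astype(int)
    for k in range(len(c) - 1):
        rr, cc, val = line_aa(r[k], c[k], r[k + 1], c[k + 1])
        inside = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        np.maximum.at(img, (rr[inside], cc[inside]), val[inside] * intensity)


def _draw_grid(img: np.ndarray, style: RenderStyle) -> None:
    img[:: style.grid_spacing_px, :] = np.maximum(img[:: style.grid_spacing_px, :], style.grid_intensity)
    img[:, :: style.grid_spacing_px] = np.maximum(img[:, :: style.grid_spacing_px], style.grid_intensity)


def render_capture(
    signal: CalibratedSignal,
    ecg: CalibratedSignal,
    style: RenderStyle,
    kind: str,
    seed: int | None = 0,
    r_times: np.ndarray | None = None,
) -> tuple[np.ndarray, CaptureTruth]:
    """Render a waveform + ECG strip as a clinical-style screen capture.

    ``kind`` is ``"pressure_trace"`` (bright anti-aliased polyline) or
    ``"doppler_spectrogram"`` (filled band from the zero-velocity baseline
    up to the envelope, with seeded speckle).  Returns the image array in
    [0, 1] plus a :class:`CaptureTruth` bundle with the exact calibration
    anchors and per-column pixel paths.
    """
    if kind not in ("pressure_trace", "doppler_spectrogram"):
        raise InputError(f"unknown capture kind {kind!r}")
    rng = np.random.default_rng(seed)
    dur = min(signal.duration, ecg.duration)
    width = int(np.floor(dur * style.px_per_second)) + 1
    if width < 2:
        raise RenderError("signal too short for the configured sweep speed")
    if width > 20000:
        raise RenderError("signal longer than drawable width (reduce duration or sweep speed)")
    img = np.full((style.height_px, width), style.background)
    _draw_grid(img, style)

    cols = np.arange(width)
    t_cols = signal.t0 + cols / style.px_per_second

    # --- waveform region calibration -------------------------------------
    vmin, vmax = float(np.min(signal.values)), float(np.max(signal.values))
    span = max(vmax - vmin, 1e-6)
    top_row, bot_row = style.waveform_top, style.waveform_bottom - 1
    if kind == "doppler_spectrogram":
        # baseline (zero velocity) sits at the region bottom; envelope above
        v_top = vmax + style.value_margin * span
        cal = _affine_cal(0.0, signal.t0, style.px_per_second, top_row, v_top, bot_row, 0.0, signal.unit)
        baseline_row = bot_row
        region = RegionSpec(
            left=1, top=style.waveform_top, right=width - 1, bottom=style.waveform_bottom,
            trace_kind="doppler_envelope", envelope_direction="above_baseline",
            baseline_row=baseline_row,
        )
    else:
        v_top = vmax + style.value_margin * span
        v_bot = vmin - style.value_margin * span
        cal = _affine_cal(0.0, signal.t0, style.px_per_second, top_row, v_top, bot_row, v_bot, signal.unit)
        # the outermost column on each side is excluded: only one polyline
        # segment lands there, which biases the centroid on steep slopes
        region = RegionSpec(
            left=1, top=style.waveform_top, right=width - 1, bottom=style.waveform_bottom,
            trace_kind="line_trace",
        )

    sig_at_cols = np.interp(t_cols, signal.times, signal.values)
    path_rows = np.asarray(cal.value_to_row(sig_at_cols), dtype=float)

    if kind == "doppler_spectrogram":
        env_rows = np.clip(np.round(path_rows).astype(int), style.waveform_top, bot_row)
        for c in cols:
            band = np.arange(env_rows[c], bot_row + 1)
            vals = style.band_intensity * (0.75 + 0.25 * rng.random(band.size))
            if style.speckle_density > 0 and band.size:
                # speckle dropout lives inside the band; the outermost pixel
                # (the maximum-velocity edge itself) is part of the envelope
                drop = rng.random(band.size) < style.speckle_density
                drop[0] = False
                vals[drop] = style.background
            vals[-1] = max(vals[-1], style.band_intensity)  # zero-line clutter stays visible
            img[band, c] = np.maximum(img[band, c], vals)
        if style.salt_density > 0:
            outside = np.zeros_like(img, dtype=bool)
            outside[style.waveform_top:style.waveform_bottom, :] = True
            for c in cols:
                outside[env_rows[c]:bot_row + 1, c] = False
            salt = outside & (rng.random(img.shape) < style.salt_density)
            img[salt] = np.maximum(img[salt], style.band_intensity)
    else:
        _draw_polyline(img, cols, path_rows, style.trace_intensity)

    # --- ECG strip --------------------------------------------------------
    e_min, e_max = float(np.min(ecg.values)), float(np.max(ecg.values))
    e_span = max(e_max - e_min, 1e-6)
    e_top, e_bot = style.ecg_top, style.ecg_bottom - 1
    ecg_cal = _affine_cal(
        0.0, ecg.t0, style.px_per_second,
        e_top, e_max + style.value_margin * e_span,
        e_bot, e_min - style.value_margin * e_span,
        "a.u.",
    )
    ecg_at_cols = np.interp(t_cols, ecg.times, ecg.values)
    ecg_rows = np.asarray(ecg_cal.value_to_row(ecg_at_cols), dtype=float)
    _draw_polyline(img, cols, ecg_rows, style.trace_intensity)
    ecg_region = RegionSpec(left=1, top=style.ecg_top, right=width - 1, bottom=style.ecg_bottom, trace_kind="ecg")

    if style.noise_sigma > 0:
        img = img + rng.normal(0.0, style.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = CaptureTruth(
        waveform_region=region,
        ecg_region=ecg_region,
        waveform_cal=cal,
        ecg_cal=ecg_cal,
        true_path_rows=path_rows,
        ecg_path_rows=ecg_rows,
        r_times=None if r_times is None else np.asarray(r_times, dtype=float),
    )
    return img, truth


# ---------------------------------------------------------------------------
# full fixture sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSession:
    """Paths and ground truth of one rendered fixture study stage."""

    session_config: Path
    pressure_image: Path
    doppler_image: Path
    truth_file: Path
    wk: WindkesselParams
    pulse: FlowPulseParams
    pa_diameter_cm: float
    analytic: dict  # analytic tpr/zc/zs/fundamental at the nominal heart rate


def random_fixture_params(rng: np.random.Generator) -> tuple[WindkesselParams, FlowPulseParams, float]:
    """Draw Windkessel + pulse parameters from the physiologic ranges."""
    lo, hi = PHYSIOLOGIC_RANGES["Rc"]
    rc = rng.uniform(lo, hi)
    lo, hi = PHYSIOLOGIC_RANGES["Rp"]
    rp = rng.uniform(max(lo, 4 * rc), hi)
    lo, hi = PHYSIOLOGIC_RANGES["C"]
    c = rng.uniform(lo, hi)
    lo, hi = PHYSIOLOGIC_RANGES["heart_rate"]
    hr = rng.uniform(lo, hi)
    lo, hi = PHYSIOLOGIC_RANGES["stroke_volume"]
    sv = rng.uniform(lo, hi)
    wk = WindkesselParams(Rc=rc, Rp=rp, C=c)
    pulse = FlowPulseParams(heart_rate=hr, stroke_volume=sv)
    diameter = rng.uniform(1.8, 2.8)  # cm, adult main PA at the pulmonic valve
    return wk, pulse, diameter


def analytic_parameters(wk: WindkesselParams, heart_rate: float,
                        zc_range: tuple[int, int] = (2, 4),
                        zs_indices: tuple[int, int] = (1, 2)) -> dict:
    """Closed-form TPR/Zc/Zs of the Windkessel at a given heart rate."""
    f1 = heart_rate / 60.0
    mods = {k: abs(analytic_impedance(wk, k * f1)) for k in range(0, max(zc_range[1], zs_indices[1]) + 1)}
    zc = float(np.mean([mods[k] for k in range(zc_range[0], zc_range[1] + 1)]))
    zs = float(mods[zs_indices[0]] + mods[zs_indices[1]])
    return {"tpr": wk.Rc + wk.Rp, "zc": zc, "zs": zs, "fundamental_hz": f1}


def _anchors_json(cal: AxisCalibration) -> dict:
    return {
        "x_anchors": [list(a) for a in cal.x_anchors],
        "y_anchors": [list(a) for a in cal.y_anchors],
        "unit": cal.unit,
    }


def make_fixture_session(
    out_dir: str | Path,
    seed: int = 0,
    wk: WindkesselParams | None = None,
    pulse: FlowPulseParams | None = None,
    pa_diameter_cm: float | None = None,
    duration: float = 6.0,
    noise: bool = True,
    stage_label: str = "stage-1",
) -> FixtureSession:
    """Render one complete study stage and write a ready-to-run session config.

    Writes ``pressure.png``, ``doppler.png``, a ground-truth JSON bundle
    and ``session.yaml`` into ``out_dir``.  With ``noise=True`` the Doppler
    band carries 10% speckle, images get mild background noise, and beats
    get 2% R-R jitter; with ``noise=False`` rendering is clean and beats
    strictly periodic.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if wk is None or pulse is None or pa_diameter_cm is None:
        rwk, rpulse, rdiam = random_fixture_params(rng)
        wk = wk or rwk
        pulse = pulse or rpulse
        pa_diameter_cm = pa_diameter_cm or rdiam
    if noise and pulse.hr_jitter == 0.0:
        pulse = FlowPulseParams(
            heart_rate=pulse.heart_rate, stroke_volume=pulse.stroke_volume,
            ejection_fraction_of_cycle=pulse.ejection_fraction_of_cycle, hr_jitter=0.02,
        )

    style_kw = dict(speckle_density=0.10, noise_sigma=0.03) if noise else {}
    style = RenderStyle(**style_kw)

    area = np.pi * pa_diameter_cm**2 / 4.0

    # pressure capture (independent beat-timing realization)
    flow_p, r_p = simulate_flow(pulse, duration, seed=int(rng.integers(2**31)))
    pressure = apply_windkessel(flow_p, wk)
    ecg_p, _ = simulate_ecg(pulse.heart_rate, duration, r_times=r_p)
    img_p, truth_p = render_capture(pressure, ecg_p, style, "pressure_trace",
                                    seed=int(rng.integers(2**31)), r_times=r_p)

    # doppler capture (its own, asynchronous beat-timing realization)
    flow_d, r_d = simulate_flow(pulse, duration, seed=int(rng.integers(2**31)))
    velocity = flow_d.scaled(1.0 / area, unit="cm/s", label="PA velocity")
    ecg_d, _ = simulate_ecg(pulse.heart_rate, duration, r_times=r_d)
    img_d, truth_d = render_capture(velocity, ecg_d, style, "doppler_spectrogram",
                                    seed=int(rng.integers(2**31)), r_times=r_d)

    p_path = out / "pressure.png"
    d_path = out / "doppler.png"
    for img, path in ((img_p, p_path), (img_d, d_path)):
        Image.fromarray((img * 255.0).round().astype(np.uint8), mode="L").save(path)

    analytic = analytic_parameters(wk, pulse.heart_rate)
    truth_file = out / "truth.json"
    truth_file.write_text(json.dumps({
        "windkessel": asdict(wk),
        "pulse": asdict(pulse),
        "pa_diameter_cm": pa_diameter_cm,
        "analytic": analytic,
        "r_times_pressure": r_p.tolist(),
        "r_times_doppler": r_d.tolist(),
        "pressure_true_path": truth_p.true_path_rows.tolist(),
        "doppler_true_path": truth_d.true_path_rows.tolist(),
    }, indent=1))

    def capture_block(path: Path, truth: CaptureTruth, doppler: bool) -> dict:
        wr = truth.waveform_region
        block = {
            "image": path.name,
            "waveform_region": {"left": wr.left, "top": wr.top, "right": wr.right, "bottom": wr.bottom},
            "ecg_region": {
                "left": truth.ecg_region.left, "top": truth.ecg_region.top,
                "right": truth.ecg_region.right, "bottom": truth.ecg_region.bottom,
            },
            "waveform_calibration": _anchors_json(truth.waveform_cal),
            "ecg_calibration": _anchors_json(truth.ecg_cal),
        }
        if doppler:
            block["baseline_row"] = wr.baseline_row
            block["envelope_direction"] = wr.envelope_direction
        return block

    config = {
        "schema_version": 1,
        "stages": [{
            "label": stage_label,
            "pa_diameter_cm": float(pa_diameter_cm),
            "pressure": capture_block(p_path, truth_p, doppler=False),
            "doppler": capture_block(d_path, truth_d, doppler=True),
        }],
    }
    session_config = out / "session.yaml"
    session_config.write_text(yaml.safe_dump(config, sort_keys=False))
    return FixtureSession(
        session_config=session_config,
        pressure_image=p_path,
        doppler_image=d_path,
        truth_file=truth_file,
        wk=wk,
        pulse=pulse,
        pa_diameter_cm=float(pa_diameter_cm),
        analytic=analytic,
    )
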