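"""Study orchestration: config parsing, per-stage pipeline, exports.

A *session* is one patient study: an ordered list of stages (e.g. the
phases of an intervention), each pairing one PA-pressure capture with one
pulsed-wave Doppler capture plus the echo-measured PA diameter.  The
session config is a single human-editable YAML file documented in
``docs/methods.md``; it replaces an interactive GUI with reviewable,
versionable inputs.

Per stage the pipeline runs: digitize -> calibrate -> resample (1000 Hz)
-> R peaks -> segment -> select -> ARB for both captures; flow from
velocity x CSA; harmonic decomposition; PVZ spectrum; TPR/Zc/Zs.  Because
the two captures are asynchronous, their heart rates are compared and a
warning (never a failure) is attached when they differ by more than the
configured tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import beats as bt
from . import digitizer as dg
from . import impedance as imp
from .errors import ConfigError, InputError, PvzError

__all__ = [
    "CaptureConfig",
    "StageConfig",
    "SessionConfig",
    "StageResult",
    "load_session",
    "check_hr_match",
    "run_stage",
    "run_session",
    "overlay_spectra",
    "export_table",
    "export_spectra",
]

log = logging.getLogger("pvzkit")


# ---------------------------------------------------------------------------
# config schema (pydantic)
# ---------------------------------------------------------------------------

class RegionModel(BaseModel):
    left: int
    top: int
    right: int
    bottom: int


class CalibrationModel(BaseModel):
    x_anchors: tuple[tuple[float, float], tuple[float, float]]
    y_anchors: tuple[tuple[float, float], tuple[float, float]]
    unit: str


class CaptureConfig(BaseModel):
    """One capture: image path, regions, calibrations, detection options."""

    image: str
    waveform_region: RegionModel
    ecg_region: RegionModel
    waveform_calibration: CalibrationModel
    ecg_calibration: CalibrationModel
    baseline_row: int | None = None
    envelope_direction: str = "above_baseline"
    include_beats: list[int] | None = None  # 0-based; None = all detected
    detection_threshold: float = Field(default=dg.DEFAULT_THRESHOLD, gt=0.0, lt=1.0)
    invert_ecg: bool = False


class StageConfig(BaseModel):
    """One study stage: a pressure/doppler capture pair plus PA geometry."""

    label: str
    pressure: CaptureConfig
    doppler: CaptureConfig
    pa_diameter_cm: float = Field(gt=0.0)
    hr_mismatch_tolerance: float = Field(default=0.10, gt=0.0, lt=1.0)


class SessionConfig(BaseModel):
    schema_version: int = 1
    stages: list[StageConfig] = Field(min_length=1)

    @field_validator("schema_version")
    @classmethod
    def _known_version(cls, v: int) -> int:
        if v != 1:
            raise ValueError(f"unsupported schema_version {v}")
        return v


def load_session(path: str | Path) -> tuple[SessionConfig, Path]:
    """Parse and validate a session config; returns (config, base directory).

    Image paths in the config are resolved relative to the config file.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"session config not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse session config {p}: {exc}") from exc
    try:
        cfg = SessionConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        where = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"invalid session config {p}: {where}: {first['msg']}") from exc
    base = p.parent
    for stage in cfg.stages:
        for cap in (stage.pressure, stage.doppler):
            img = base / cap.image
            if not img.exists():
                raise InputError(f"stage {stage.label!r}: capture image not found: {img}")
    return cfg, base


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class StageResult:
    label: str
    spectrum: imp.PVZSpectrum
    parameters: imp.PVZParameters
    hr_pressure: float
    hr_doppler: float
    warnings: list[str] = field(default_factory=list)
    intermediates: dict = field(default_factory=dict)  # audit trail per capture


def check_hr_match(hr_pressure: float, hr_doppler: float, tolerance: float = 0.10) -> str | None:
    """Warn (never fail) when asynchronous captures disagree on heart rate."""
    mean_hr = 0.5 * (hr_pressure + hr_doppler)
    frac = abs(hr_pressure - hr_doppler) / mean_hr
    if frac > tolerance:
        return (
            f"heart-rate mismatch: pressure {hr_pressure:.1f} vs doppler {hr_doppler:.1f} bpm "
            f"({frac:.1%} > {tolerance:.0%} tolerance); harmonics are paired by index, "
            "interpret the spectrum with care"
        )
    return None


def _tagged(exc: PvzError, stage: str, capture: str) -> PvzError:
    return type(exc)(f"stage {stage!r}, {capture} capture: {exc}")


def _digitize_capture(cap: CaptureConfig, base: Path, stage: str, name: str, doppler: bool) -> dict:
    """Digitize one capture: waveform signal, ECG, R peaks, ARB."""
    try:
        image = dg.load_capture(base / cap.image, kind="doppler" if doppler else "pressure")
        wr = cap.waveform_region
        if doppler:
            region = dg.RegionSpec(wr.left, wr.top, wr.right, wr.bottom,
                                   trace_kind="doppler_envelope",
                                   envelope_direction=cap.envelope_direction,
                                   baseline_row=cap.baseline_row)
            raw = dg.detect_doppler_envelope(image, region, cap.detection_threshold)
        else:
            region = dg.RegionSpec(wr.left, wr.top, wr.right, wr.bottom, trace_kind="line_trace")
            raw = dg.detect_line_trace(image, region, cap.detection_threshold)
        wcal = dg.AxisCalibration(cap.waveform_calibration.x_anchors,
                                  cap.waveform_calibration.y_anchors,
                                  cap.waveform_calibration.unit)
        signal = dg.resample_uniform(dg.calibrate_trace(dg.fill_gaps(raw), wcal, label=name))

        er = cap.ecg_region
        ecg_region = dg.RegionSpec(er.left, er.top, er.right, er.bottom, trace_kind="ecg")
        ecg_raw = dg.detect_line_trace(image, ecg_region, cap.detection_threshold)
        ecal = dg.AxisCalibration(cap.ecg_calibration.x_anchors,
                                  cap.ecg_calibration.y_anchors,
                                  cap.ecg_calibration.unit)
        ecg = dg.resample_uniform(dg.calibrate_trace(dg.fill_gaps(ecg_raw), ecal, label="ECG"))

        peaks = bt.detect_r_peaks(ecg, invert=cap.invert_ecg)
        beatset = bt.segment_beats(signal, peaks)
        if cap.include_beats is not None:
            beatset = bt.select_beats(beatset, set(cap.include_beats))
        arb = bt.average_beats(beatset)
    except PvzError as exc:
        raise _tagged(exc, stage, name) from exc
    log.info("stage %s | %s: HR %.1f bpm, %d/%d beats, mean %.3g %s",
             stage, name, peaks.heart_rate, len(beatset.included), len(beatset.beats),
             float(arb.values.mean()), arb.unit)
    return {"signal": signal, "ecg": ecg, "peaks": peaks, "beats": beatset, "arb": arb}


def run_stage(
    stage: StageConfig,
    base: Path | str = ".",
    n_harmonics: int = imp.DEFAULT_N_HARMONICS,
    zc_range: tuple[int, int] = imp.DEFAULT_ZC_RANGE,
    zs_indices: tuple[int, int] = imp.DEFAULT_ZS_INDICES,
    reliable_max: int = imp.DEFAULT_RELIABLE_MAX,
) -> StageResult:
    """Run the full pipeline for one stage; deterministic for fixed inputs."""
    base = Path(base)
    pres = _digitize_capture(stage.pressure, base, stage.label, "pressure", doppler=False)
    dopp = _digitize_capture(stage.doppler, base, stage.label, "doppler", doppler=True)

    cs = imp.csa_from_diameter(stage.pa_diameter_cm)
    flow_arb = imp.flow_from_velocity(dopp["arb"], cs)
    p_spec = imp.decompose_harmonics(pres["arb"], n_harmonics)
    q_spec = imp.decompose_harmonics(flow_arb, n_harmonics)
    try:
        spectrum = imp.compute_pvz(p_spec, q_spec, reliable_max)
        params = imp.derive_parameters(spectrum, zc_range, zs_indices)
    except PvzError as exc:
        raise type(exc)(f"stage {stage.label!r}: {exc}") from exc

    warnings: list[str] = []
    hr_p = pres["peaks"].heart_rate
    hr_d = dopp["peaks"].heart_rate
    warn = check_hr_match(hr_p, hr_d, stage.hr_mismatch_tolerance)
    if warn:
        warnings.append(warn)
        log.warning("stage %s | %s", stage.label, warn)
    log.info("stage %s | TPR %.3f  Zc %.3f  Zs %.3f mmHg*s/mL (f1 %.2f Hz)",
             stage.label, params.tpr, params.zc, params.zs, params.fundamental_hz)
    return StageResult(
        label=stage.label,
        spectrum=spectrum,
        parameters=params,
        hr_pressure=hr_p,
        hr_doppler=hr_d,
        warnings=warnings,
        intermediates={"pressure": pres, "doppler": dopp, "flow_arb": flow_arb, "csa": cs},
    )


def run_session(config_path: str | Path, **stage_kwargs) -> list[StageResult]:
    """Load a session config and run every stage in file order."""
    cfg, base = load_session(config_path)
    return [run_stage(stage, base, **stage_kwargs) for stage in cfg.stages]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def overlay_spectra(results: list[StageResult], output_path: str | Path) -> Path:
    """Overlay the stages' PVZ spectra: modulus and phase vs harmonic index.

    Harmonics beyond the catheter-fidelity limit are shaded.
    """
    if not results:
        raise InputError("no stage results to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_m, ax_p) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for res in results:
        k = np.arange(res.spectrum.n_harmonics + 1)
        ax_m.plot(k, res.spectrum.modulus, marker="o", label=res.label)
        ax_p.plot(k[1:], res.spectrum.phase_deg, marker="o", label=res.label)
    rel = min(r.spectrum.reliable_max_harmonic for r in results)
    n_max = max(r.spectrum.n_harmonics for r in results)
    for ax in (ax_m, ax_p):
        if rel < n_max:
            ax.axvspan(rel + 0.5, n_max + 0.5, color="0.85", zorder=0,
                       label="beyond catheter fidelity" if ax is ax_m else None)
        ax.set_xlim(-0.5, n_max + 0.5)
    ax_m.set_ylabel("PVZ modulus (mmHg·s/mL)")
    ax_p.set_ylabel("PVZ phase (°)")
    ax_p.set_xlabel("harmonic index z(n)")
    ax_m.legend()
    fig.tight_layout()
    out = Path(output_path)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


_ALT_UNIT_LABEL = {"dyn_s_cm5": "dyn·s·cm⁻⁵", "wood": "Wood units", "mmHg_s_ml": "mmHg·s/mL"}


def export_table(results: list[StageResult], output_path: str | Path, alt_unit: str = "wood") -> Path:
    """Write the per-stage parameter table as CSV."""
    if not results:
        raise InputError("no stage results to export")
    rows = []
    for r in results:
        p = r.parameters
        row = {
            "stage": r.label,
            "hr_pressure_bpm": r.hr_pressure,
            "hr_doppler_bpm": r.hr_doppler,
            "fundamental_hz": p.fundamental_hz,
            "tpr_mmHg_s_ml": p.tpr,
            "zc_mmHg_s_ml": p.zc,
            "zs_mmHg_s_ml": p.zs,
        }
        if alt_unit != "mmHg_s_ml":
            for name, val in (("tpr", p.tpr), ("zc", p.zc), ("zs", p.zs)):
                row[f"{name}_{alt_unit}"] = imp.convert_impedance_units(val, alt_unit)
        row["warnings"] = "; ".join(r.warnings)
        rows.append(row)
    out = Path(output_path)
    try:
        pd.DataFrame(rows).to_csv(out, index=False)
    except OSError as exc:
        raise InputError(f"cannot write parameter table {out}: {exc}") from exc
    return out


def export_spectra(results: list[StageResult], output_path: str | Path) -> Path:
    """Write the per-harmonic spectra (all stages) as one long-format CSV."""
    if not results:
        raise InputError("no stage results to export")
    rows = []
    for r in results:
        s = r.spectrum
        for k in range(s.n_harmonics + 1):
            rows.append({
                "stage": r.label,
                "harmonic": k,
                "frequency_hz": k * s.fundamental_hz_pressure,
                "p_modulus_mmHg": s.p_modulus[k],
                "q_modulus_ml_s": s.q_modulus[k],
                "pvz_modulus_mmHg_s_ml": s.modulus[k],
                "pvz_phase_deg": s.phase_deg[k - 1] if k >= 1 else "",
                "reliable": k <= s.reliable_max_harmonic,
            })
    out = Path(output_path)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def export_json(results: list[StageResult], output_path: str | Path) -> Path:
    """Write a machine-readable result bundle (spectra + parameters)."""
    if not results:
        raise InputError("no stage results to export")
    payload = []
    for r in results:
        s, p = r.spectrum, r.parameters
        payload.append({
            "stage": r.label,
            "heart_rate_bpm": {"pressure": r.hr_pressure, "doppler": r.hr_doppler},
            "warnings": r.warnings,
            "spectrum": {
                "modulus_mmHg_s_ml": s.modulus.tolist(),
                "phase_deg": s.phase_deg.tolist(),
                "fundamental_hz_pressure": s.fundamental_hz_pressure,
                "fundamental_hz_flow": s.fundamental_hz_flow,
                "reliable_max_harmonic": s.reliable_max_harmonic,
            },
            "parameters": {
                "tpr_mmHg_s_ml": p.tpr, "zc_mmHg_s_ml": p.zc, "zs_mmHg_s_ml": p.zs,
                "fundamental_hz": p.fundamental_hz,
                "zc_harmonics": list(p.zc_harmonics), "zs_harmonics": list(p.zs_harmonics),
            },
        })
    out = Path(output_path)
    out.write_text(json.dumps(payload, indent=1))
    return out
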