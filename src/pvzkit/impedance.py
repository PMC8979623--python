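"""Frequency-domain pulmonary vascular impedance (PVZ).

The pulmonary circulation presents the right ventricle with both a steady
and a pulsatile load.  The impedance spectrum captures both: decompose
the average pressure beat P and the average flow beat Q into harmonics of
the heart rate, and form, harmonic by harmonic,

    |PVZ(k)| = |P(k)| / |Q(k)|,     phase(k) = arg P(k) - arg Q(k).

Because the pressure and Doppler captures are acquired asynchronously,
harmonics are paired strictly by index k, never by absolute frequency:
harmonic 1 of the pressure beat is matched with harmonic 1 of the flow
beat even when the two captures were taken at slightly different heart
rates.

Derived scalars:

* TPR (total pulmonary resistance) = |PVZ(0)| = mean P / mean Q,
* Zc  (characteristic impedance)   = mean of |PVZ(k)| over k = 2..4,
* Zs  (stiffness index)            = |PVZ(1)| + |PVZ(2)|.

Fluid-filled catheters limit the usable bandwidth; the spectrum carries a
``reliable_max_harmonic`` marker (default 3) as metadata — higher
harmonics are still computed and reported, only flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beats import AverageBeat
from .errors import DataError, DegenerateFlowError, InputError, RangeError, UnitError

__all__ = [
    "CrossSection",
    "HarmonicSpectrum",
    "PVZSpectrum",
    "PVZParameters",
    "csa_from_diameter",
    "flow_from_velocity",
    "decompose_harmonics",
    "compute_pvz",
    "derive_parameters",
    "convert_impedance_units",
    "wrap_phase_deg",
    "DEFAULT_N_HARMONICS",
    "DEFAULT_RELIABLE_MAX",
    "DEFAULT_ZC_RANGE",
    "DEFAULT_ZS_INDICES",
]

DEFAULT_N_HARMONICS = 10
#: Fluid-filled Swan-Ganz catheters are trustworthy up to about the 3rd harmonic.
DEFAULT_RELIABLE_MAX = 3
DEFAULT_ZC_RANGE = (2, 4)  # inclusive harmonic range averaged for Zc
DEFAULT_ZS_INDICES = (1, 2)  # harmonics summed for Zs

#: Relative cutoff below which a flow harmonic is treated as numerically zero.
_DEGENERATE_REL = 1e-12


@dataclass(frozen=True)
class CrossSection:
    """Pulmonary-artery cross section at the pulmonic valve (circular)."""

    diameter: float  # cm
    area: float  # cm^2


@dataclass(frozen=True)
class HarmonicSpectrum:
    """One-sided complex harmonic amplitudes of an ARB.

    ``amplitudes[0]`` is the (real) signal mean; for k >= 1,
    ``amplitudes[k] = (2/L) * sum_j x_j exp(-2*pi*i*k*j/L)`` so that
    ``abs(amplitudes[k])`` is the physical cosine amplitude of harmonic k
    at frequency ``k * fundamental_hz``.
    """

    fundamental_hz: float
    amplitudes: np.ndarray  # complex, index 0..N
    unit: str

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=complex)
        if self.fundamental_hz <= 0:
            raise DataError("fundamental frequency must be positive")
        if amps.size < 2:
            raise DataError("a spectrum needs harmonic 0 and at least harmonic 1")
        if abs(amps[0].imag) > 1e-12 * max(1.0, abs(amps[0].real)):
            raise DataError("harmonic 0 must be real (the signal mean)")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_harmonics(self) -> int:
        return self.amplitudes.size - 1


@dataclass(frozen=True)
class PVZSpectrum:
    """Impedance modulus and phase difference per harmonic index."""

    modulus: np.ndarray  # mmHg*s/mL, index 0..N
    phase_deg: np.ndarray  # degrees in (-180, 180], index 1..N
    fundamental_hz_pressure: float
    fundamental_hz_flow: float
    reliable_max_harmonic: int
    p_modulus: np.ndarray  # |P(k)|, mmHg
    q_modulus: np.ndarray  # |Q(k)|, mL/s

    @property
    def n_harmonics(self) -> int:
        return self.modulus.size - 1


@dataclass(frozen=True)
class PVZParameters:
    """Scalar afterload parameters derived from one PVZ spectrum."""

    tpr: float  # mmHg*s/mL, modulus at harmonic 0
    zc: float  # mmHg*s/mL
    zs: float  # mmHg*s/mL
    fundamental_hz: float
    zc_harmonics: tuple[int, int]  # inclusive range averaged
    zs_harmonics: tuple[int, int]  # pair summed


def csa_from_diameter(diameter: float) -> CrossSection:
    """Circular cross-sectional area pi*d^2/4 (cm^2) from echo diameter (cm)."""
    if not (diameter > 0):
        raise InputError(f"PA diameter must be positive, got {diameter}")
    return CrossSection(diameter=float(diameter), area=math.pi * diameter**2 / 4.0)


def flow_from_velocity(velocity: AverageBeat, cs: CrossSection) -> AverageBeat:
    """Volumetric flow Q(t) = V(t) x CSA, cm/s x cm^2 -> mL/s."""
    if velocity.unit not in ("cm/s", "cm s^-1"):
        raise UnitError(f"velocity ARB must be in cm/s, got {velocity.unit!r}")
    return velocity.scaled(cs.area, unit="mL/s")


def decompose_harmonics(beat: AverageBeat, n_harmonics: int = DEFAULT_N_HARMONICS) -> HarmonicSpectrum:
    """FFT harmonic decomposition of an ARB.

    Returns one-sided physical amplitudes: harmonic 0 is the mean, and
    for k >= 1 the complex amplitude is ``(2/L) * DFT_k`` so its modulus
    equals the cosine amplitude of that harmonic.  The fundamental is
    1/period — the ARB spans exactly one cardiac cycle by construction.
    """
    x = np.asarray(beat.values, dtype=float)
    L = x.size
    if n_harmonics < 1:
        raise InputError("n_harmonics must be at least 1")
    if L < 2 * n_harmonics + 1:
        raise InputError(
            f"beat of {L} samples supports at most {(L - 1) // 2} harmonics, requested {n_harmonics}"
        )
    f = np.fft.rfft(x)
    amps = np.empty(n_harmonics + 1, dtype=complex)
    amps[0] = f[0].real / L
    amps[1:] = 2.0 / L * f[1:n_harmonics + 1]
    return HarmonicSpectrum(fundamental_hz=1.0 / beat.period, amplitudes=amps, unit=beat.unit)


def wrap_phase_deg(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase in degrees into (-180, 180]."""
    wrapped = -((-np.asarray(phase, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def compute_pvz(
    p: HarmonicSpectrum,
    q: HarmonicSpectrum,
    reliable_max: int = DEFAULT_RELIABLE_MAX,
) -> PVZSpectrum:
    """Impedance spectrum as the per-harmonic ratio of pressure to flow.

    Harmonics are matched by index k regardless of the actual frequencies
    of the two (asynchronously captured) beats; both fundamentals are
    recorded so the mismatch stays visible downstream.  Phase difference
    is pressure phase minus flow phase, wrapped to (-180, 180]: a negative
    low-harmonic phase means flow leads pressure.
    """
    n = min(p.n_harmonics, q.n_harmonics)
    pa = p.amplitudes[: n + 1]
    qa = q.amplitudes[: n + 1]
    q0 = qa[0].real
    if q0 <= 0:
        raise DataError(f"mean flow must be positive, got {q0:.4g} {q.unit}")
    qmag = np.abs(qa)
    floor = _DEGENERATE_REL * qmag[1]
    dead = np.flatnonzero(qmag <= floor)
    if dead.size:
        raise DegenerateFlowError(
            f"flow harmonic {int(dead[0])} is numerically zero; impedance undefined at that index"
        )
    modulus = np.abs(pa) / qmag
    modulus[0] = pa[0].real / q0
    phase = wrap_phase_deg(np.degrees(np.angle(pa[1:]) - np.angle(qa[1:])))
    return PVZSpectrum(
        modulus=modulus,
        phase_deg=np.atleast_1d(phase),
        fundamental_hz_pressure=p.fundamental_hz,
        fundamental_hz_flow=q.fundamental_hz,
        reliable_max_harmonic=min(reliable_max, n),
        p_modulus=np.abs(pa),
        q_modulus=qmag,
    )


def derive_parameters(
    spec: PVZSpectrum,
    zc_range: tuple[int, int] = DEFAULT_ZC_RANGE,
    zs_indices: tuple[int, int] = DEFAULT_ZS_INDICES,
) -> PVZParameters:
    """TPR, Zc and Zs from a PVZ spectrum.

    TPR is the zeroth modulus (mean pressure over mean flow); Zc averages
    the moduli over the inclusive ``zc_range`` (default 2..4, the
    high-frequency plateau a fluid-filled catheter can still resolve); Zs
    sums the moduli at ``zs_indices`` (default harmonics 1 and 2).
    """
    lo, hi = int(zc_range[0]), int(zc_range[1])
    i1, i2 = int(zs_indices[0]), int(zs_indices[1])
    n = spec.n_harmonics
    if lo < 0 or lo > hi or hi > n or max(i1, i2) > n or min(i1, i2) < 0:
        raise RangeError(
            f"requested harmonics (Zc {lo}..{hi}, Zs {i1},{i2}) beyond computed spectrum 0..{n}"
        )
    zc = float(spec.modulus[lo:hi + 1].mean())
    zs = float(spec.modulus[i1] + spec.modulus[i2])
    return PVZParameters(
        tpr=float(spec.modulus[0]),
        zc=zc,
        zs=zs,
        fundamental_hz=spec.fundamental_hz_pressure,
        zc_harmonics=(lo, hi),
        zs_harmonics=(i1, i2),
    )


#: mmHg*s/mL -> dyn*s*cm^-5 (1 mmHg = 1333.22 dyn/cm^2; 1 mL = 1 cm^3).
_TO_DYN = 1333.22
#: mmHg*s/mL -> Wood units (mmHg*min/L): x 1000 mL/L / 60 s/min.
_TO_WOOD = 1000.0 / 60.0

_UNIT_FACTORS = {
    "mmHg_s_ml": 1.0,
    "dyn_s_cm5": _TO_DYN,
    "wood": _TO_WOOD,
}


def convert_impedance_units(value: float, target: str) -> float:
    """Convert an impedance/resistance from mmHg*s/mL to a clinical unit."""
    if target not in _UNIT_FACTORS:
        raise UnitError(f"unknown impedance unit {target!r}; expected one of {sorted(_UNIT_FACTORS)}")
    if not np.isfinite(value) or value < 0:
        raise InputError(f"impedance value must be finite and nonnegative, got {value}")
    return float(value) * _UNIT_FACTORS[target]
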