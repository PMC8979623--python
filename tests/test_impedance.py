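"""Harmonic decomposition, impedance spectrum and derived parameters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvzkit as pv
from pvzkit.beats import AverageBeat
from pvzkit.errors import DataError, DegenerateFlowError, InputError, RangeError, UnitError
from pvzkit.impedance import wrap_phase_deg
from pvzkit.synthetic import analytic_impedance

from conftest import naive_dft_amplitudes, peaks_from_times


def _beat(values, period=1.0, unit="mmHg", rate=None):
    values = np.asarray(values, dtype=float)
    rate = values.size / period if rate is None else rate
    return AverageBeat(values=values, rate=rate, period=period, n_beats=1, unit=unit)


class TestCrossSection:
    def test_circle_area_2cm(self):
        cs = pv.csa_from_diameter(2.0)
        assert cs.area == pytest.approx(3.14159, abs=1e-5)

    def test_circle_area_1cm(self):
        assert pv.csa_from_diameter(1.0).area == pytest.approx(0.785398, abs=1e-6)

    @pytest.mark.parametrize("d", [0.0, -1.0])
    def test_nonpositive_diameter_rejected(self, d):
        with pytest.raises(InputError):
            pv.csa_from_diameter(d)


class TestFlowFromVelocity:
    def test_constant_velocity_scales_by_area(self):
        v = _beat(np.full(100, 50.0), unit="cm/s")
        q = pv.flow_from_velocity(v, pv.CrossSection(diameter=2.2568, area=4.0))
        assert np.allclose(q.values, 200.0)
        assert q.unit == "mL/s"
        assert q.period == v.period and q.rate == v.rate

    def test_zero_velocity_gives_zero_flow(self):
        q = pv.flow_from_velocity(_beat(np.zeros(50), unit="cm/s"), pv.csa_from_diameter(2.0))
        assert np.all(q.values == 0.0)

    def test_halfsine_peak_scales(self):
        v = _beat(100.0 * np.sin(np.pi * np.linspace(0, 1, 200)), unit="cm/s")
        q = pv.flow_from_velocity(v, pv.csa_from_diameter(2.0))
        assert q.values.max() == pytest.approx(314.159, abs=0.01)

    def test_wrong_unit_rejected(self):
        with pytest.raises(UnitError):
            pv.flow_from_velocity(_beat(np.ones(50), unit="m/s"), pv.csa_from_diameter(2.0))


class TestDecompose:
    def test_constant_beat(self):
        spec = pv.decompose_harmonics(_beat(np.full(100, 7.5)), n_harmonics=3)
        assert spec.amplitudes[0] == pytest.approx(7.5)
        assert np.allclose(np.abs(spec.amplitudes[1:]), 0.0, atol=1e-12)

    def test_single_tone_amplitude_and_phase(self):
        t = np.arange(1000) / 1000.0
        x = 5.0 + 3.0 * np.cos(2 * np.pi * t - np.radians(30.0))
        spec = pv.decompose_harmonics(_beat(x, period=1.0), n_harmonics=4)
        assert spec.amplitudes[0] == pytest.approx(5.0, abs=1e-9)
        assert abs(spec.amplitudes[1]) == pytest.approx(3.0, abs=1e-9)
        assert np.degrees(np.angle(spec.amplitudes[1])) == pytest.approx(-30.0, abs=1e-6)
        assert np.max(np.abs(spec.amplitudes[2:])) <= 1e-6
        assert spec.fundamental_hz == pytest.approx(1.0)

    def test_matches_naive_dft_on_random_beat(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        spec = pv.decompose_harmonics(_beat(x), n_harmonics=31)
        oracle = naive_dft_amplitudes(x, 31)
        assert np.allclose(spec.amplitudes, oracle, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError, match="harmonics"):
            pv.decompose_harmonics(_beat(np.ones(10)), n_harmonics=5)

    def test_reconstruction_from_harmonics(self):
        """mean + sum of Re(a_k e^{2 pi i k j / L}) reproduces a band-limited beat."""
        rng = np.random.default_rng(1)
        L = 128
        j = np.arange(L)
        x = 2.0 + sum(
            rng.uniform(0.5, 2) * np.cos(2 * np.pi * k * j / L + rng.uniform(-np.pi, np.pi))
            for k in range(1, 10)
        )
        n = L // 2 - 1
        spec = pv.decompose_harmonics(_beat(x), n_harmonics=n)
        recon = np.full(L, spec.amplitudes[0].real)
        for k in range(1, n + 1):
            recon += np.real(spec.amplitudes[k] * np.exp(2j * np.pi * k * j / L))
        assert np.sqrt(np.mean((recon - x) ** 2)) <= 1e-6


class TestComputePvz:
    def _tone_pair(self, p_amp, p_phase_deg, q_amp, q_phase_deg, L=1000):
        j = np.arange(L) / L
        p = 10 + p_amp * np.cos(2 * np.pi * j + np.radians(p_phase_deg))
        q = 20 + q_amp * np.cos(2 * np.pi * j + np.radians(q_phase_deg))
        return (
            pv.decompose_harmonics(_beat(p, unit="mmHg"), 1),
            pv.decompose_harmonics(_beat(q, unit="mL/s"), 1),
        )

    def test_pure_resistance(self):
        rng = np.random.default_rng(2)
        q_vals = 50 + 10 * rng.standard_normal(500)
        p_vals = 1.05 * q_vals
        ps = pv.decompose_harmonics(_beat(p_vals, unit="mmHg"), 8)
        qs = pv.decompose_harmonics(_beat(q_vals, unit="mL/s"), 8)
        spec = pv.compute_pvz(ps, qs)
        assert np.allclose(spec.modulus, 1.05, rtol=1e-9)
        assert np.allclose(spec.phase_deg, 0.0, atol=1e-7)

    def test_single_tone_ratio_and_phase(self):
        ps, qs = self._tone_pair(6.0, 0.0, 3.0, 45.0)
        spec = pv.compute_pvz(ps, qs)
        assert spec.modulus[1] == pytest.approx(2.0, rel=1e-9)
        assert spec.phase_deg[0] == pytest.approx(-45.0, abs=1e-9)

    def test_modulus0_is_ratio_of_means(self):
        rng = np.random.default_rng(3)
        p_vals, q_vals = rng.random(400) + 3, rng.random(400) + 5
        ps = pv.decompose_harmonics(_beat(p_vals, unit="mmHg"), 3)
        qs = pv.decompose_harmonics(_beat(q_vals, unit="mL/s"), 3)
        spec = pv.compute_pvz(ps, qs)
        assert spec.modulus[0] == pytest.approx(p_vals.mean() / q_vals.mean(), rel=1e-12)

    def test_harmonic_index_pairing_ignores_frequency(self):
        """Spectra from beats with different periods (heart rates) pair by
        index: moduli and phases are unchanged by the period mismatch."""
        j1 = np.arange(1000) / 1000.0
        p = 10 + 4 * np.cos(2 * np.pi * j1 - 0.5)
        q_same = 20 + 8 * np.cos(2 * np.pi * j1 + 0.3)
        ps = pv.decompose_harmonics(_beat(p, period=1.0, unit="mmHg"), 1)
        qs_same = pv.decompose_harmonics(_beat(q_same, period=1.0, unit="mL/s"), 1)
        j2 = np.arange(750) / 750.0
        q_fast = 20 + 8 * np.cos(2 * np.pi * j2 + 0.3)  # same shape, 80 bpm vs 60
        qs_fast = pv.decompose_harmonics(_beat(q_fast, period=0.75, unit="mL/s"), 1)
        a = pv.compute_pvz(ps, qs_same)
        b = pv.compute_pvz(ps, qs_fast)
        assert b.modulus == pytest.approx(a.modulus, rel=1e-9)
        assert b.phase_deg == pytest.approx(a.phase_deg, abs=1e-9)
        assert b.fundamental_hz_flow == pytest.approx(1.0 / 0.75)

    def test_degenerate_flow_harmonic_rejected(self):
        # flow with zero 2nd harmonic content
        j = np.arange(1000) / 1000.0
        q = 20 + 5 * np.cos(2 * np.pi * j)
        p = 10 + 3 * np.cos(2 * np.pi * j) + 1 * np.cos(4 * np.pi * j)
        ps = pv.decompose_harmonics(_beat(p, unit="mmHg"), 2)
        qs = pv.decompose_harmonics(_beat(q, unit="mL/s"), 2)
        with pytest.raises(DegenerateFlowError, match="harmonic 2"):
            pv.compute_pvz(ps, qs)

    def test_nonpositive_mean_flow_rejected(self):
        j = np.arange(1000) / 1000.0
        p = 10 + np.cos(2 * np.pi * j)
        q = -5 + np.cos(2 * np.pi * j)
        ps = pv.decompose_harmonics(_beat(p, unit="mmHg"), 1)
        qs = pv.decompose_harmonics(_beat(q, unit="mL/s"), 1)
        with pytest.raises(DataError, match="mean flow"):
            pv.compute_pvz(ps, qs)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(0.1, 10.0), b=st.floats(0.1, 10.0))
    def test_scale_covariance(self, a, b):
        """Scaling pressure by a scales moduli by a; scaling flow by b scales
        them by 1/b; phases are unchanged either way."""
        rng = np.random.default_rng(7)
        p_vals = 15 + np.cumsum(rng.standard_normal(256)) * 0.1
        q_vals = 30 + np.cumsum(rng.standard_normal(256)) * 0.1
        ps = pv.decompose_harmonics(_beat(p_vals, unit="mmHg"), 5)
        qs = pv.decompose_harmonics(_beat(q_vals, unit="mL/s"), 5)
        base = pv.compute_pvz(ps, qs)
        ps_a = pv.decompose_harmonics(_beat(p_vals * a, unit="mmHg"), 5)
        qs_b = pv.decompose_harmonics(_beat(q_vals * b, unit="mL/s"), 5)
        scaled = pv.compute_pvz(ps_a, qs_b)
        assert np.allclose(scaled.modulus, base.modulus * a / b, rtol=1e-9)
        assert np.allclose(scaled.phase_deg, base.phase_deg, atol=1e-9)


class TestDeriveParameters:
    def test_documented_modulus_example(self):
        spec = _spec_from_modulus([3.0, 1.0, 0.6, 0.5, 0.4])
        params = pv.derive_parameters(spec)
        assert params.tpr == 3.0
        assert params.zs == pytest.approx(1.6)
        assert params.zc == pytest.approx(0.5)

    def test_flat_spectrum(self):
        params = pv.derive_parameters(_spec_from_modulus([0.8] * 5))
        assert params.tpr == pytest.approx(0.8)
        assert params.zc == pytest.approx(0.8)
        assert params.zs == pytest.approx(1.6)

    def test_out_of_range_harmonics_rejected(self):
        with pytest.raises(RangeError):
            pv.derive_parameters(_spec_from_modulus([3.0, 1.0, 0.6, 0.5, 0.4]), zc_range=(2, 5))

    def test_configurable_ranges(self):
        spec = _spec_from_modulus([3.0, 1.0, 0.6, 0.5, 0.4])
        params = pv.derive_parameters(spec, zc_range=(3, 4), zs_indices=(0, 1))
        assert params.zc == pytest.approx(0.45)
        assert params.zs == pytest.approx(4.0)


def _spec_from_modulus(modulus):
    m = np.asarray(modulus, dtype=float)
    return pv.PVZSpectrum(
        modulus=m,
        phase_deg=np.zeros(m.size - 1),
        fundamental_hz_pressure=1.0,
        fundamental_hz_flow=1.0,
        reliable_max_harmonic=3,
        p_modulus=m.copy(),
        q_modulus=np.ones_like(m),
    )


class TestUnits:
    def test_dyn_conversion(self):
        assert pv.convert_impedance_units(1.0, "dyn_s_cm5") == pytest.approx(1333.22)

    def test_wood_conversion(self):
        assert pv.convert_impedance_units(1.0, "wood") == pytest.approx(16.667, abs=1e-3)

    def test_zero_is_zero_everywhere(self):
        for unit in ("mmHg_s_ml", "dyn_s_cm5", "wood"):
            assert pv.convert_impedance_units(0.0, unit) == 0.0

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            pv.convert_impedance_units(1.0, "psi")


@settings(derandomize=True, max_examples=60)
@given(st.floats(-2000.0, 2000.0))
def test_phase_wrap_lands_in_half_open_interval(phi):
    w = float(wrap_phase_deg(phi))
    assert -180.0 < w <= 180.0
    # congruent modulo 360
    assert abs((w - phi) % 360.0) < 1e-9 or abs((w - phi) % 360.0 - 360.0) < 1e-9


class TestWindkesselRecovery:
    """Core-pipeline oracle: Windkessel-generated P,Q recover the analytic Z."""

    def test_noiseless_recovery_within_one_percent(self, windkessel, pulse_60, wk_pair):
        pressure, flow, r_times = wk_pair
        peaks = peaks_from_times(r_times)
        qb = pv.average_beats(pv.segment_beats(flow, peaks))
        pb = pv.average_beats(pv.segment_beats(pressure, peaks))
        spec = pv.compute_pvz(pv.decompose_harmonics(pb, 6), pv.decompose_harmonics(qb, 6))
        f1 = 1.0 / qb.period
        for k in range(5):
            z = analytic_impedance(windkessel, k * f1)
            assert spec.modulus[k] == pytest.approx(abs(z), rel=0.01)
            if k >= 1:
                assert spec.phase_deg[k - 1] == pytest.approx(np.degrees(np.angle(z)), abs=1.0)
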