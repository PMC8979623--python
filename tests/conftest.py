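"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pvzkit.beats import RPeakSeries
from pvzkit.synthetic import (
    FlowPulseParams,
    WindkesselParams,
    apply_windkessel,
    make_fixture_session,
    simulate_flow,
)


def naive_dft_amplitudes(x: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Defining-sum DFT oracle: brute-force evaluation, independent of FFT.

    amplitude[0] = mean(x); amplitude[k] = (2/L) * sum_j x_j e^{-2 pi i k j / L}.
    """
    x = np.asarray(x, dtype=float)
    L = x.size
    j = np.arange(L)
    out = np.empty(n_harmonics + 1, dtype=complex)
    out[0] = x.mean()
    for k in range(1, n_harmonics + 1):
        out[k] = 2.0 / L * np.sum(x * np.exp(-2j * np.pi * k * j / L))
    return out


def peaks_from_times(r_times: np.ndarray) -> RPeakSeries:
    """Build an RPeakSeries directly from ground-truth R times."""
    rr = float(np.diff(r_times).mean())
    return RPeakSeries(peak_times=np.asarray(r_times, dtype=float), mean_rr=rr, heart_rate=60.0 / rr)


@pytest.fixture()
def windkessel() -> WindkesselParams:
    return WindkesselParams(Rc=0.05, Rp=0.7, C=3.0)


@pytest.fixture()
def pulse_60() -> FlowPulseParams:
    return FlowPulseParams(heart_rate=60.0, stroke_volume=70.0)


@pytest.fixture()
def wk_pair(windkessel, pulse_60):
    """Noiseless, strictly periodic pressure/flow record pair + true R times."""
    flow, r_times = simulate_flow(pulse_60, 6.0, seed=0)
    pressure = apply_windkessel(flow, windkessel)
    return pressure, flow, r_times


@pytest.fixture(scope="session")
def noiseless_fixture_dir(tmp_path_factory):
    """One rendered fixture stage with clean rendering and periodic beats."""
    out = tmp_path_factory.mktemp("fixture_clean")
    return make_fixture_session(
        out,
        seed=7,
        wk=WindkesselParams(Rc=0.05, Rp=0.7, C=3.0),
        pulse=FlowPulseParams(heart_rate=72.0, stroke_volume=70.0),
        pa_diameter_cm=2.2,
        noise=False,
    )


@pytest.fixture(scope="session")
def noisy_fixture_dir(tmp_path_factory):
    """One rendered fixture stage with speckle, image noise and R-R jitter."""
    out = tmp_path_factory.mktemp("fixture_noisy")
    return make_fixture_session(out, seed=11, noise=True)
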