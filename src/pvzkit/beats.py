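"""ECG-gated beat segmentation and signal averaging.

The ECG strip co-captured with each waveform provides the only clock the
asynchronous captures share, so beats are delimited strictly by the R-R
interval: each beat runs from one R peak to the next.  Included beats are
time-normalized to the mean R-R interval and averaged point-wise into an
average representative beat (ARB), the object the frequency-domain
analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError, DetectionError, SelectionError
from .digitizer import CalibratedSignal

__all__ = [
    "RPeakSeries",
    "Beat",
    "BeatSet",
    "AverageBeat",
    "detect_r_peaks",
    "segment_beats",
    "select_beats",
    "average_beats",
]


@dataclass(frozen=True)
class RPeakSeries:
    """Detected R-peak times (s) with the derived rhythm summary."""

    peak_times: np.ndarray  # strictly increasing, on the sample grid
    mean_rr: float  # s
    heart_rate: float  # beats/min, = 60 / mean_rr

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        if t.size < 2:
            raise DetectionError("an R-peak series needs at least 2 peaks")
        if not np.all(np.diff(t) > 0):
            raise DataError("R-peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", t)


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle of a hemodynamic signal, R peak to R peak."""

    values: np.ndarray
    duration: float  # s, the beat's R-R interval
    index: int  # ordinal within its capture


@dataclass(frozen=True)
class BeatSet:
    """Segmented beats plus the investigator's include/exclude selection."""

    beats: tuple[Beat, ...]
    rate: float
    unit: str
    included: frozenset[int]

    def __post_init__(self) -> None:
        avail = {b.index for b in self.beats}
        if not self.included or not set(self.included) <= avail:
            raise SelectionError(
                f"included beats {sorted(self.included)} must be a nonempty subset of {sorted(avail)}"
            )

    @property
    def included_beats(self) -> list[Beat]:
        return [b for b in self.beats if b.index in self.included]


@dataclass(frozen=True)
class AverageBeat:
    """Average representative beat (ARB): one time-normalized mean cycle."""

    values: np.ndarray
    rate: float
    period: float  # s, mean R-R of the included beats
    n_beats: int
    unit: str

    def __post_init__(self) -> None:
        if self.period <= 0 or self.n_beats < 1:
            raise DataError("ARB requires positive period and at least one beat")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def scaled(self, factor: float, unit: str | None = None) -> "AverageBeat":
        return replace(self, values=self.values * factor, unit=self.unit if unit is None else unit)


def detect_r_peaks(
    ecg: CalibratedSignal,
    refractory: float = 0.3,
    rel_threshold: float = 0.6,
    invert: bool = False,
    amplitude_percentile: float = 99.5,
) -> RPeakSeries:
    """Detect R peaks with a relative amplitude threshold.

    The ECG is detrended by subtracting its median; candidate peaks are
    local maxima above ``rel_threshold`` times a robust maximum (the
    ``amplitude_percentile``-th percentile of the detrended signal, which
    reaches the QRS spikes at physiologic duty cycles while ignoring
    isolated glitches).  Candidates are accepted tallest-first subject to
    the ``refractory`` spacing (0.3 s admits rhythms up to 200 bpm).
    The relative threshold makes detection invariant to amplitude scaling.

    ``invert=True`` flips the signal first, for negative-polarity leads.
    """
    x = np.asarray(ecg.values, dtype=float)
    if invert:
        x = -x
    if (x.size - 1) / ecg.rate < 2.0:
        raise DataError("ECG shorter than 2 s: cannot establish rhythm")
    x = x - np.median(x)
    amp = np.percentile(x, amplitude_percentile)
    if amp <= 0:
        raise DetectionError("cannot segment beats: flat ECG (no positive amplitude)")
    height = rel_threshold * amp
    distance = max(1, int(round(refractory * ecg.rate)))
    idx, _ = find_peaks(x, height=height, distance=distance)
    if idx.size < 2:
        raise DetectionError("cannot segment beats: fewer than 2 R peaks detected")
    times = ecg.t0 + idx / ecg.rate
    rr = np.diff(times)
    mean_rr = float(rr.mean())
    return RPeakSeries(peak_times=times, mean_rr=mean_rr, heart_rate=60.0 / mean_rr)


def segment_beats(signal: CalibratedSignal, peaks: RPeakSeries) -> BeatSet:
    """Cut a signal into beats at the R peaks; partial cycles are discarded.

    The signal and the peaks must share a time base (same capture).  Each
    complete ``[R_i, R_{i+1})`` window becomes one beat; all beats start
    included.
    """
    n = signal.values.size
    idx = np.round((peaks.peak_times - signal.t0) * signal.rate).astype(int)
    beats: list[Beat] = []
    for k in range(idx.size - 1):
        i0, i1 = idx[k], idx[k + 1]
        if i0 < 0 or i1 > n:
            continue  # partial cycle outside the signal span
        beats.append(
            Beat(
                values=signal.values[i0:i1].copy(),
                duration=(i1 - i0) / signal.rate,
                index=len(beats),
            )
        )
    if not beats:
        raise DetectionError("no complete cardiac cycle inside the signal span")
    return BeatSet(
        beats=tuple(beats),
        rate=signal.rate,
        unit=signal.unit,
        included=frozenset(b.index for b in beats),
    )


def select_beats(beats: BeatSet, include: set[int] | frozenset[int]) -> BeatSet:
    """Return a new BeatSet with the given inclusion; the input is unchanged."""
    return replace(beats, included=frozenset(include))


def average_beats(beats: BeatSet) -> AverageBeat:
    """Build the ARB: time-normalize included beats to the mean R-R, then average.

    Each included beat is linearly resampled to ``round(mean R-R x rate)``
    samples, which aligns systolic and diastolic phases across beats of
    unequal length, then the beats are averaged point-wise.
    """
    chosen = beats.included_beats
    mean_rr = float(np.mean([b.duration for b in chosen]))
    target_len = int(round(mean_rr * beats.rate))
    if target_len < 2:
        raise DataError("mean beat shorter than 2 samples")
    phase = np.linspace(0.0, 1.0, target_len)
    stack = np.empty((len(chosen), target_len))
    for i, b in enumerate(chosen):
        src_phase = np.linspace(0.0, 1.0, b.values.size)
        stack[i] = np.interp(phase, src_phase, b.values)
    return AverageBeat(
        values=stack.mean(axis=0),
        rate=beats.rate,
        period=mean_rr,
        n_beats=len(chosen),
        unit=beats.unit,
    )
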