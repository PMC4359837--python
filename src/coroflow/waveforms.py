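"""Synthesis and I/O of single-cycle pressure and velocity waveforms.

Stands in for intracoronary combo-wire recordings: one cardiac cycle of
aortic-side pressure at the inlet and Doppler velocity at the distal
(outlet) location, sampled on a uniform grid.  The generator is a
truncated Fourier series with a systolic-weighted phase template, so the
shape has a single dominant systolic peak while the cycle mean is
prescribed exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class WaveformError(ValueError):
    pass


@dataclass
class Waveform:
    """Sampled periodic time series over one cardiac cycle.

    ``times`` must be a uniform, strictly increasing grid covering one
    full period including both endpoints.  ``values`` are mmHg for
    ``kind='pressure'`` and m/s for ``kind='velocity'`` (non-negative).
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    kind: str = "pressure"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self):
        t, v = self.times, self.values
        if t.ndim != 1 or len(t) < 2 or len(t) != len(v):
            raise WaveformError("times/values must be 1D of equal length >= 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise WaveformError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise WaveformError("times must be uniformly spaced")
        if not np.isclose(t[-1] - t[0], self.period, rtol=1e-9):
            raise WaveformError("times must span exactly one period")
        if not np.all(np.isfinite(v)):
            raise WaveformError("values must be finite")
        if self.kind == "velocity" and np.any(v < 0):
            raise WaveformError("velocity waveform has negative values")
        if self.kind not in ("pressure", "velocity"):
            raise WaveformError(f"unknown waveform kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def at(self, t: float) -> float:
        """Periodic linear interpolation at time ``t``."""
        tau = (t - self.times[0]) % self.period
        return float(np.interp(tau, self.times - self.times[0], self.values))

    def resample(self, dt: float) -> "Waveform":
        n = int(round(self.period / dt))
        if not np.isclose(n * dt, self.period, rtol=1e-9):
            raise WaveformError("dt must divide the period")
        t = self.times[0] + dt * np.arange(n + 1)
        v = np.interp(t - self.times[0], self.times - self.times[0],
                      self.values)
        return Waveform(t, v, self.period, self.kind)


@dataclass
class WaveformSpec:
    """Parameters of the synthetic waveform generator.

    ``mean`` sets the exact (noise-free) cycle mean; ``pulse_amplitude``
    the peak-to-trough excursion; harmonics shape a single systolic peak
    with the diastolic decay typical of aortic pressure.  ``cycle_index``
    is retained for multi-cycle wire traces and unused by the generator.
    """

    kind: str = "pressure"
    mean: float = 100.0            # mmHg or m/s
    pulse_amplitude: float = 40.0  # peak-to-trough, same units
    period: float = 0.8            # s
    n_harmonics: int = 4
    harmonic_weights: Optional[Sequence[float]] = None
    harmonic_phases: Optional[Sequence[float]] = None
    noise_sd: float = 0.0
    seed: int = 0
    cycle_index: int = 2

    def __post_init__(self):
        if self.mean <= 0:
            raise WaveformError(f"mean must be > 0, got {self.mean}")
        if self.pulse_amplitude < 0:
            raise WaveformError("pulse_amplitude must be >= 0")
        if self.period <= 0:
            raise WaveformError("period must be > 0")
        if self.noise_sd < 0:
            raise WaveformError("noise_sd must be >= 0")


#: default harmonic template: amplitudes fall off ~1/k, phases delay the
#: peak into early systole (t/T ~ 0.25); shared by pressure and velocity.
_DEF_W = np.array([1.0, 0.55, 0.28, 0.12])
_DEF_PH = np.array([-1.88, -3.2, -4.3, -5.3])


def synth_waveform(spec: WaveformSpec, dt: float = 0.05) -> Waveform:
    """Generate one cardiac cycle on a uniform grid of step ``dt``.

    The noise-free series has trapezoidal cycle mean exactly
    ``spec.mean``; optional additive Gaussian noise (``noise_sd``,
    ``seed``) is applied afterwards and clipped at zero for velocity.
    """
    n = round(spec.period / dt)
    if n < 1 or not np.isclose(n * dt, spec.period, rtol=0, atol=1e-9):
        raise WaveformError(
            f"dt={dt} must divide the period {spec.period} (got {n} steps)"
        )
    if dt >= spec.period:
        raise WaveformError("dt must be smaller than the period")
    t = dt * np.arange(n + 1)
    w = np.array(spec.harmonic_weights if spec.harmonic_weights is not None
                 else _DEF_W[: spec.n_harmonics], dtype=float)
    ph = np.array(spec.harmonic_phases if spec.harmonic_phases is not None
                  else _DEF_PH[: spec.n_harmonics], dtype=float)
    k = min(len(w), len(ph), spec.n_harmonics)
    shape = np.zeros_like(t)
    for j in range(k):
        shape += w[j] * np.cos(2 * np.pi * (j + 1) * t / spec.period + ph[j])
    # remove the discrete trapezoidal mean of the shape, then scale the
    # peak-to-trough excursion to the requested pulse amplitude
    if k and spec.pulse_amplitude > 0:
        shape -= np.trapezoid(shape, t) / spec.period
        ptp = shape.max() - shape.min()
        vals = spec.mean + spec.pulse_amplitude / ptp * shape
    else:
        vals = np.full_like(t, spec.mean)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
    if spec.kind == "velocity":
        vals = np.clip(vals, 0.0, None)
    return Waveform(t, vals, spec.period, spec.kind)


def cycle_mean(w: Waveform) -> float:
    """Time-weighted (trapezoidal) mean of one cycle."""
    return float(np.trapezoid(w.values, w.times) / w.period)


def write_waveform_csv(w: Waveform, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(w.times, w.values):
            writer.writerow([f"{t:.12g}", f"{v:.12g}"])


def read_waveform_csv(path, kind: str = "pressure") -> Waveform:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0].strip() != "time_s":
            raise WaveformError(
                f"{path}: expected header 'time_s,value', got {header!r}"
            )
        rows = [(float(r[0]), float(r[1])) for r in reader if r]
    if len(rows) < 2:
        raise WaveformError(f"{path}: needs at least two samples")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    period = float(t[-1] - t[0])
    return Waveform(t, v, period, kind)
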