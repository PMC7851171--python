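"""Beam intensity-vs-time profiles (pulse trains).

Covers the pulse structures used across the study: square single pulses and
25-cycle bursts from the chopped tandem beam, the few-µs Gaussian pulse of a
synchro-cyclotron, and the quasi-continuous synchrotron spill with its MHz
micro-structure (Gaussian micro-pulses every 228 ns whose amplitudes
fluctuate with Poisson statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dose import ELEMENTARY_CHARGE

__all__ = [
    "PulseTrain",
    "square_pulse_train",
    "gaussian_pulse",
    "synchrotron_burst",
    "ACQUISITION_SAMPLING_HZ",
]

ACQUISITION_SAMPLING_HZ = 156.25e6
_BASE_DT = 1.0 / ACQUISITION_SAMPLING_HZ

# synchrotron spill defaults
SYNCHROTRON_SIGMA_MICRO = 19.75e-9  # s
SYNCHROTRON_PERIOD_MICRO = 228e-9  # s -> 4.39 MHz repetition
SYNCHROTRON_RATE = 3.2e9  # protons / s
SYNCHROTRON_BURST = 50e-3  # s


@dataclass
class PulseTrain:
    """Beam intensity vs time on a uniform grid [protons/s]."""

    intensity: np.ndarray
    dt: float
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.intensity.size) * self.dt

    @property
    def total_protons(self) -> float:
        return float(self.intensity.sum() * self.dt)

    @property
    def total_charge(self) -> float:
        return self.total_protons * ELEMENTARY_CHARGE

    def resampled(self, dt_new: float) -> "PulseTrain":
        """Charge-preserving resampling onto a new uniform step."""
        if abs(dt_new - self.dt) < 1e-18:
            return self
        n_new = int(np.ceil(self.intensity.size * self.dt / dt_new)) + 1
        edges_new = np.arange(n_new + 1) * dt_new
        cum = np.concatenate(([0.0], np.cumsum(self.intensity) * self.dt))
        edges_old = np.arange(self.intensity.size + 1) * self.dt
        w = np.diff(np.interp(edges_new, edges_old, cum, right=cum[-1])) / dt_new
        return PulseTrain(w, dt_new, self.kind, dict(self.parameters), self.seed)


def _coverage(t_edges: np.ndarray, a: float, b: float) -> np.ndarray:
    """Fraction of each bin covered by the interval [a, b]."""
    lo = np.clip(t_edges[:-1], a, b)
    hi = np.clip(t_edges[1:], a, b)
    return (hi - lo) / np.diff(t_edges)


def square_pulse_train(
    width: float,
    period: float,
    n_cycles: int = 1,
    protons_per_pulse: float = 2.8e6,
    dt: float = _BASE_DT,
) -> PulseTrain:
    """Rectangular pulses: ``n_cycles`` pulses of ``width`` every ``period``.

    Bin edges are handled by fractional coverage, so the time integral equals
    n_cycles x protons_per_pulse to machine precision.
    """
    if not 0 < width <= period:
        raise ValueError("require 0 < width <= period")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n = int(np.ceil(((n_cycles - 1) * period + width) / dt)) + 1
    edges = np.arange(n + 1) * dt
    rate = protons_per_pulse / width
    intensity = np.zeros(n)
    for k in range(n_cycles):
        intensity += rate * _coverage(edges, k * period, k * period + width)
    return PulseTrain(
        intensity, dt, "square_burst" if n_cycles > 1 else "square_single",
        {"width_s": width, "period_s": period, "n_cycles": n_cycles,
         "duty": width / period, "protons_per_pulse": protons_per_pulse},
    )


def gaussian_pulse(
    protons: float,
    sigma: float | None = None,
    fwhm: float | None = None,
    dt: float = _BASE_DT,
    truncate: float = 5.0,
) -> PulseTrain:
    """Gaussian pulse (synchro-cyclotron), truncated at ±truncate·σ and
    renormalized so the integral equals ``protons`` exactly."""
    if (sigma is None) == (fwhm is None):
        raise ValueError("give exactly one of sigma or fwhm")
    if sigma is None:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if sigma <= 0:
        raise ValueError("pulse width must be > 0")
    half = truncate * sigma
    t = np.arange(0.0, 2 * half + dt, dt)
    prof = np.exp(-0.5 * ((t - half) / sigma) ** 2)
    if protons == 0:
        return PulseTrain(np.zeros_like(prof), dt, "gaussian", {"sigma_s": sigma, "protons": 0.0})
    prof *= protons / (prof.sum() * dt)
    return PulseTrain(prof, dt, "gaussian", {"sigma_s": sigma, "protons": protons})


def synchrotron_burst(
    duration: float = SYNCHROTRON_BURST,
    sigma_micro: float = SYNCHROTRON_SIGMA_MICRO,
    period_micro: float = SYNCHROTRON_PERIOD_MICRO,
    rate: float = SYNCHROTRON_RATE,
    seed: int = 0,
    dt: float | None = None,
    arrival_jitter: bool = False,
) -> PulseTrain:
    """Stochastic synchrotron spill micro-structure.

    Gaussian micro-pulses (σ = ``sigma_micro``) arrive every ``period_micro``
    over the burst; each amplitude is scaled by an independent Poisson(1)
    draw, so the integral equals rate x duration in expectation.  The time
    step is refined below the acquisition step until ≥ 8 samples per σ.
    With ``arrival_jitter`` the arrival times themselves are additionally
    jittered by the micro-pulse σ (off by default).
    """
    if duration < period_micro:
        raise ValueError("duration must cover at least one micro-pulse period")
    if dt is None:
        # integer refinement of the acquisition step to >= 8 samples per sigma
        factor = max(1, int(np.ceil(_BASE_DT / (sigma_micro / 8.0))))
        dt = _BASE_DT / factor
    rng = np.random.default_rng(seed)
    n_micro = int(np.floor(duration / period_micro))
    protons_per_micro = rate * period_micro
    amplitudes = rng.poisson(1.0, n_micro) * protons_per_micro

    arrivals = (np.arange(n_micro) + 0.5) * period_micro
    if arrival_jitter:
        arrivals = arrivals + rng.normal(0.0, sigma_micro, n_micro)

    n = int(np.ceil((duration + 8 * sigma_micro) / dt))
    counts = np.zeros(n)
    # charge-preserving two-bin split of each arrival
    pos = arrivals / dt - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, n - 1)
    frac = pos - np.floor(pos)
    np.add.at(counts, i0, amplitudes * (1.0 - frac))
    np.add.at(counts, np.clip(i0 + 1, 0, n - 1), amplitudes * frac)
    counts = gaussian_filter1d(counts, sigma_micro / dt, mode="constant", truncate=6.0)
    return PulseTrain(
        counts / dt, dt, "synchrotron",
        {"duration_s": duration, "sigma_micro_s": sigma_micro,
         "period_micro_s": period_micro, "rate_protons_per_s": rate,
         "n_micro_pulses": n_micro, "pulse_repetition_hz": 1.0 / period_micro,
         "arrival_jitter": arrival_jitter},
        seed=seed,
    )
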