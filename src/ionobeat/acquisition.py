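"""Synthetic measurement campaign: noisy acquisitions and grouped statistics.

The experimental protocol records 3000 acquisitions per configuration,
averages them offline, and quotes uncertainties from 30 sub-measurements
(each the average of 100 acquisitions) at 99% confidence.  This module
emulates that pipeline on simulated traces with additive white Gaussian
detector noise, so every analysis stage can be exercised and calibrated
without beam time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import t as t_dist

from .acoustics import PressureTrace

__all__ = ["MeasurementSet", "GroupedStats", "simulate_acquisitions", "grouped_stats"]


@dataclass
class MeasurementSet:
    """n noisy realizations of a base trace on a shared time axis."""

    base: PressureTrace
    traces: np.ndarray  # (n, len) Pa
    noise_sigma: float
    seed: int
    beam_position: np.ndarray | None = None  # optional per-acquisition label

    @property
    def n_acquisitions(self) -> int:
        return self.traces.shape[0]

    def mean_trace(self) -> PressureTrace:
        return self.base.copy_with(self.traces.mean(axis=0), averaged_over=self.n_acquisitions)


@dataclass
class GroupedStats:
    """Per-group statistic values with mean and 99% confidence half-width."""

    values: np.ndarray  # one value per group
    mean: float
    ci99_half_width: float
    n_groups: int
    group_size: int
    confidence: float = 0.99

    def __post_init__(self):
        if self.ci99_half_width < 0:
            raise ValueError("half-width must be >= 0")


def simulate_acquisitions(
    base: PressureTrace,
    noise_sigma: float,
    n: int = 3000,
    seed: int = 0,
    jitter_weights: tuple | None = None,
) -> MeasurementSet:
    """n independent noisy copies of ``base`` (additive white Gaussian noise).

    ``jitter_weights`` optionally assigns each acquisition a beam-position
    label drawn from ``((offset, weight), ...)``; the traces themselves are
    unchanged (position-resolved simulation happens upstream in the dose
    model), the labels only support position-stratified analyses.
    """
    if n < 1:
        raise ValueError("need at least one acquisition")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        traces = base.p[None, :] + rng.normal(0.0, noise_sigma, (n, base.p.size))
    else:
        traces = np.tile(base.p, (n, 1))
    positions = None
    if jitter_weights is not None:
        offs = np.array([o for o, _ in jitter_weights])
        w = np.array([wt for _, wt in jitter_weights])
        positions = rng.choice(offs, size=n, p=w / w.sum())
    return MeasurementSet(base, traces, noise_sigma, seed, beam_position=positions)


def grouped_stats(
    mset: MeasurementSet,
    statistic: Callable[[PressureTrace], float],
    n_groups: int = 30,
    group_size: int = 100,
    confidence: float = 0.99,
) -> GroupedStats:
    """Statistic on group-averaged traces with a t-based confidence interval.

    The acquisitions are partitioned in order into ``n_groups`` groups of
    ``group_size``; the statistic (e.g. an :func:`amplitude_at_frequency` or
    :func:`phase_shift` wrapper) is evaluated on each group mean, and the
    spread across groups gives the confidence half-width
    t_{(1+conf)/2, n_groups-1} · s / sqrt(n_groups).
    """
    if n_groups * group_size > mset.n_acquisitions:
        raise ValueError("insufficient acquisitions for the requested grouping")
    vals = np.empty(n_groups)
    for g in range(n_groups):
        block = mset.traces[g * group_size : (g + 1) * group_size].mean(axis=0)
        vals[g] = statistic(mset.base.copy_with(block, group=g))
    sd = float(np.std(vals, ddof=1)) if n_groups > 1 else 0.0
    tcrit = float(t_dist.ppf(0.5 + confidence / 2.0, n_groups - 1))
    return GroupedStats(
        values=vals,
        mean=float(vals.mean()),
        ci99_half_width=tcrit * sd / np.sqrt(n_groups),
        n_groups=n_groups,
        group_size=group_size,
        confidence=confidence,
    )
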