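"""Synthetic growth/division time courses.

Population model: exponential proliferation ``N(t) = N0 * 2^(t / tau)`` with
cycle length ``tau``, and mean per-cell protein mass
``m(t) = m0 * exp((gamma - alpha) * t)`` where ``alpha = ln2 / tau`` is the
division rate and ``gamma`` the per-cell mass accumulation (synthesis) rate.
Bulk protein mass is ``M(t) = N(t) * m(t)``.  In balanced growth
(``gamma == alpha``) the mean cell mass is constant.  Measurements are
multiplied by lognormal noise of a given CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class GrowthTimecourse:
    """Replicate series of cell counts and bulk protein mass over time."""

    times: np.ndarray  # (T,) hours, strictly increasing
    counts: np.ndarray  # (R, T)
    mass: np.ndarray  # (R, T) total stain intensity, arbitrary units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.mass = np.atleast_2d(np.asarray(self.mass, dtype=float))
        if self.times.size == 0:
            raise ValueError("times must be nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.counts.shape != self.mass.shape or self.counts.shape[1] != self.times.size:
            raise ValueError("counts and mass must be (replicates, len(times))")


def generate_growth_timecourse(
    growth_rate: float,
    cycle_length: float,
    times,
    replicates: int = 2,
    noise_cv: float = 0.05,
    seed: int = 0,
    n0: float = 1000.0,
    m0: float = 1.0,
) -> GrowthTimecourse:
    """Simulate counts and bulk mass for one condition.

    Parameters
    ----------
    growth_rate
        Per-cell mass accumulation rate gamma [1/h].
    cycle_length
        Cell-cycle length tau [h]; division rate alpha = ln2 / tau.
    times
        Sampling times [h].
    replicates
        Independent measurement series (two, as in a paired-replicate assay).
    noise_cv
        CV of multiplicative lognormal measurement noise; 0 gives exact data.
    """
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    rng = np.random.default_rng(seed)
    alpha = math.log(2.0) / cycle_length
    n_true = n0 * np.exp2(times / cycle_length)
    m_true = m0 * np.exp((growth_rate - alpha) * times)
    mass_true = n_true * m_true
    counts = np.tile(n_true, (replicates, 1))
    mass = np.tile(mass_true, (replicates, 1))
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        mu = -0.5 * sigma**2
        counts = counts * rng.lognormal(mu, sigma, size=counts.shape)
        mass = mass * rng.lognormal(mu, sigma, size=mass.shape)
    return GrowthTimecourse(times=times, counts=counts, mass=mass)
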