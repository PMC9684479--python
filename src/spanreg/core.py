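"""Grids, kernel construction, signal synthesis and noise handling.

The forward model is the discretized Laplace transform

    y(t_i) = sum_j exp(-t_i / T2_j) f(T2_j) dT2,

i.e. ``y = A f`` with kernel entries ``A[i, j] = exp(-t_i/T2_j) * dT2``.
``f`` is a non-negative density on a uniform T2 grid (units 1/ms), so areas
are computed as ``sum(f) * dT2``.  The signal-to-noise ratio of an observed
decay is defined as ``max|y| / RMS(noise)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "T2Grid",
    "TimeGrid",
    "KernelMatrix",
    "DistributionFunction",
    "Signal",
    "NoiseModel",
    "NoiseEstimate",
    "make_t2_grid",
    "make_time_grid",
    "echo_train",
    "build_kernel",
    "synthesize_signal",
    "add_noise",
    "estimate_noise_sigma",
]

_UNIFORMITY_RTOL = 1e-12


@dataclass(frozen=True)
class T2Grid:
    """Uniform grid of relaxation times (ms) on which distributions live."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("T2 grid needs at least two points")
        if np.any(v <= 0):
            raise ValueError("T2 values must be strictly positive")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("T2 values must be strictly increasing")
        if np.max(np.abs(d - d[0])) > _UNIFORMITY_RTOL * max(abs(v[-1]), 1.0):
            raise ValueError("T2 grid must be uniformly spaced")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def delta(self) -> float:
        """Grid spacing dT2 in ms."""
        return float(self.values[1] - self.values[0])

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass(frozen=True)
class TimeGrid:
    """Measurement (echo) times in ms; strictly increasing, non-negative."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least two points")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def m(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KernelMatrix:
    """Discretized Laplace kernel ``A[i, j] = exp(-t_i/T2_j) * dT2``."""

    entries: np.ndarray
    time_grid: TimeGrid
    t2_grid: T2Grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def __matmul__(self, f: np.ndarray) -> np.ndarray:
        return self.entries @ np.asarray(f, dtype=float)


@dataclass(frozen=True)
class DistributionFunction:
    """Non-negative T2 density (units 1/ms) on a :class:`T2Grid`."""

    weights: np.ndarray
    grid: T2Grid

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.grid.n,):
            raise ValueError("weights must match the T2 grid length")
        if np.any(w < 0):
            raise ValueError("distribution weights must be non-negative")
        if not np.all(np.isfinite(w)):
            raise ValueError("distribution weights must be finite")

    @property
    def area(self) -> float:
        """Discrete integral sum(f)*dT2."""
        return float(self.weights.sum() * self.grid.delta)

    def normalized(self) -> "DistributionFunction":
        """Rescale to unit discrete area."""
        a = self.area
        if a <= 0:
            raise ValueError("cannot normalize a zero-area distribution")
        return DistributionFunction(self.weights / a, self.grid)


@dataclass(frozen=True)
class Signal:
    """Decay signal sampled on a :class:`TimeGrid`.

    ``sigma`` records the RMS noise amplitude when known (e.g. after
    :func:`add_noise`); ``None`` means unknown.
    """

    values: np.ndarray
    time_grid: TimeGrid
    sigma: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.time_grid.m,):
            raise ValueError("signal length must match its time grid")


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. zero-mean Gaussian noise of RMS amplitude ``sigma``."""

    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def sample(self, m: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.sigma, size=m)


def make_t2_grid(n: int, lo: float, hi: float) -> T2Grid:
    """Uniform T2 grid of ``n`` points covering [lo, hi] ms.

    The simulation default is ``make_t2_grid(200, 1, 200)``: 1 ms spacing
    over [1, 200] ms.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if lo <= 0 or hi <= lo:
        raise ValueError("require 0 < lo < hi")
    return T2Grid(np.linspace(lo, hi, n))


def make_time_grid(m: int, lo: float, hi: float) -> TimeGrid:
    """``m`` evenly spaced measurement times in [lo, hi] ms."""
    if m < 2:
        raise ValueError("m must be at least 2")
    if lo < 0 or hi <= lo:
        raise ValueError("require 0 <= lo < hi")
    return TimeGrid(np.linspace(lo, hi, m))


def echo_train(n_echoes: int, te: float) -> TimeGrid:
    """Spin-echo sampling TE_i = i*TE, i = 1..n_echoes (no t=0 sample)."""
    if n_echoes < 2:
        raise ValueError("need at least 2 echoes")
    if te <= 0:
        raise ValueError("TE must be positive")
    return TimeGrid(te * np.arange(1, n_echoes + 1, dtype=float))


def build_kernel(t: TimeGrid, tau: T2Grid) -> KernelMatrix:
    """Assemble the m-by-n exponential kernel with the dT2 quadrature weight."""
    A = np.exp(-t.times[:, None] / tau.values[None, :]) * tau.delta
    return KernelMatrix(A, t, tau)


def synthesize_signal(A: KernelMatrix, f: DistributionFunction) -> Signal:
    """Noiseless forward signal ``y = A f``."""
    if f.grid is not A.t2_grid and not np.array_equal(f.grid.values, A.t2_grid.values):
        raise ValueError("distribution grid does not match the kernel's T2 grid")
    return Signal(A.entries @ f.weights, A.time_grid, sigma=0.0)


def add_noise(
    y: Signal,
    snr: float | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> Signal:
    """Add i.i.d. Gaussian noise to a signal.

    The RMS amplitude is either taken from ``noise.sigma`` or derived from
    the requested SNR as ``sigma = max|y| / snr``.  A generator passed via
    ``rng`` takes precedence over ``noise.seed``.
    """
    if noise is not None and snr is None:
        sigma = noise.sigma
    elif snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        peak = float(np.max(np.abs(y.values)))
        if peak == 0.0:
            raise ValueError("cannot set SNR for an all-zero signal")
        sigma = peak / snr
    else:
        raise ValueError("provide either snr or a NoiseModel")
    if sigma == 0.0:
        return Signal(y.values.copy(), y.time_grid, sigma=0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else None)
    omega = rng.normal(0.0, sigma, size=y.time_grid.m)
    return Signal(y.values + omega, y.time_grid, sigma=sigma)


class NoiseEstimate(NamedTuple):
    sigma: float
    tail_not_decayed: bool


def estimate_noise_sigma(y: Signal, tail_fraction: float = 0.2) -> NoiseEstimate:
    """Estimate noise RMS from the decayed signal tail.

    Takes the last ``ceil(tail_fraction * m)`` samples, removes their mean,
    and returns the sample standard deviation.  If the tail is not noise
    dominated (tail mean exceeding 5x the tail SD) the estimate is still
    returned but flagged.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    m = y.time_grid.m
    k = int(np.ceil(tail_fraction * m))
    tail = y.values[-k:]
    mu = float(tail.mean())
    sd = float(tail.std(ddof=1)) if k > 1 else 0.0
    flagged = abs(mu) > 5.0 * sd
    if flagged:
        warnings.warn(
            "signal tail does not look noise-dominated; sigma estimate unreliable",
            stacklevel=2,
        )
    return NoiseEstimate(sigma=sd, tail_not_decayed=flagged)
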