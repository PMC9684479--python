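"""Gaussian dictionary used to represent T2 distributions.

The unknown density is expanded over unit-area Gaussian atoms
g(T2; mu_i, sigma_i) evaluated on the T2 grid.  The default dictionary is
three families with means equally spaced across the full T2 range:
160 members of SD 2 ms, 40 of SD 3 ms and 20 of SD 4 ms (M = 220).
Columns are renormalized to unit discrete area so that a simplex-weighted
combination of atoms remains a probability density despite edge truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DistributionFunction, T2Grid

__all__ = [
    "GaussianFamilySpec",
    "GaussianDictionary",
    "evaluate_gaussian",
    "build_dictionary",
    "default_families",
    "default_dictionary",
]


@dataclass(frozen=True)
class GaussianFamilySpec:
    """A family of ``count`` atoms sharing one SD, means spread over the grid."""

    count: int
    sd: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class GaussianDictionary:
    """n x M matrix of unit-area Gaussian columns with their (mu, sd) labels."""

    matrix: np.ndarray
    mus: np.ndarray
    sds: np.ndarray
    grid: T2Grid

    @property
    def m_members(self) -> int:
        return self.matrix.shape[1]

    def column(self, i: int) -> DistributionFunction:
        return DistributionFunction(self.matrix[:, i], self.grid)

    def min_distance(self, mu: float, sd: float) -> float:
        """min_i |mu - mu_i| + |sd - sd_i|; zero iff (mu, sd) is a member."""
        return float(np.min(np.abs(self.mus - mu) + np.abs(self.sds - sd)))


def evaluate_gaussian(mu: float, sd: float, grid: T2Grid) -> DistributionFunction:
    """Gaussian density with mean mu and SD sd (ms) sampled on the grid."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    x = grid.values
    w = np.exp(-((x - mu) ** 2) / (2.0 * sd**2)) / np.sqrt(2.0 * np.pi * sd**2)
    return DistributionFunction(w, grid)


def default_families() -> list[GaussianFamilySpec]:
    return [
        GaussianFamilySpec(160, 2.0),
        GaussianFamilySpec(40, 3.0),
        GaussianFamilySpec(20, 4.0),
    ]


def build_dictionary(
    grid: T2Grid, families: Sequence[GaussianFamilySpec]
) -> GaussianDictionary:
    """Assemble the dictionary matrix from family specs.

    For each family, means are placed at ``count`` equally spaced positions
    spanning the grid bounds inclusive; each column is the Gaussian density
    on the grid, renormalized to unit discrete area (sum * dT2 = 1).
    """
    if not families:
        raise ValueError("at least one family required")
    lo, hi = grid.bounds
    cols, mus, sds = [], [], []
    for fam in families:
        if fam.sd < grid.delta / 2:
            warnings.warn(
                f"family SD {fam.sd} ms is under-resolved on a {grid.delta} ms grid",
                stacklevel=2,
            )
        if fam.count == 1:
            centers = np.array([(lo + hi) / 2.0])
        else:
            centers = np.linspace(lo, hi, fam.count)
        for mu in centers:
            w = evaluate_gaussian(mu, fam.sd, grid).weights
            area = w.sum() * grid.delta
            cols.append(w / area)
            mus.append(mu)
            sds.append(fam.sd)
    G = np.column_stack(cols)
    return GaussianDictionary(G, np.array(mus), np.array(sds), grid)


def default_dictionary(grid: T2Grid) -> GaussianDictionary:
    """The 220-member dictionary (160 @ 2 ms, 40 @ 3 ms, 20 @ 4 ms)."""
    return build_dictionary(grid, default_families())
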