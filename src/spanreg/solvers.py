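"""Constrained least-squares machinery for the T2 inversion.

All solvers enforce the physical non-negativity constraint f >= 0.
Tikhonov regularization is implemented on the augmented system

    [A; lam*I] f ~ [y; 0]

so that ``nnls_tikhonov(A, y, lam)`` is exactly an NNLS solve of the
penalized objective ||A f - y||^2 + lam^2 ||f||^2.  The discrepancy
principle picks lam so that the fit residual matches the expected noise
norm nu * sqrt(m) * sigma, exploiting the monotone growth of the Tikhonov
residual in lam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .core import DistributionFunction, KernelMatrix, Signal

__all__ = [
    "LambdaLadder",
    "RegularizedFamily",
    "DPConfig",
    "DPResult",
    "nnls",
    "nnls_tikhonov",
    "regularized_family",
    "dp_select_lambda",
    "oracle_lambda_opt",
    "simplex_nnls",
]


@dataclass(frozen=True)
class LambdaLadder:
    """Strictly increasing ladder of positive regularization weights."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if np.any(v <= 0):
            raise ValueError("lambda values must be strictly positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("lambda values must be strictly increasing")

    @classmethod
    def log_spaced(cls, n: int = 16, lo: float = 1e-6, hi: float = 10.0) -> "LambdaLadder":
        """Logarithmically spaced ladder; default N=16 over [1e-6, 10]."""
        if n == 1:
            return cls(np.array([lo]))
        return cls(np.geomspace(lo, hi, n))

    @property
    def n(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


@dataclass(frozen=True)
class RegularizedFamily:
    """Tikhonov-NNLS solutions, one per ladder entry, in ladder order."""

    ladder: LambdaLadder
    solutions: tuple[DistributionFunction, ...]
    signal: Signal

    def __post_init__(self) -> None:
        if len(self.solutions) != self.ladder.n:
            raise ValueError("one solution per ladder entry required")

    def as_matrix(self) -> np.ndarray:
        """n x N matrix with f_{lambda_j} as column j."""
        return np.column_stack([f.weights for f in self.solutions])


@dataclass(frozen=True)
class DPConfig:
    """Discrepancy-principle settings: safety factor nu >= 1 and noise RMS."""

    sigma: float
    nu: float = 1.05

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError("safety factor nu must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DPResult:
    lambda_dp: float
    solution: DistributionFunction
    residual: float
    target: float
    flag: str  # "ok", "lambda_min" or "lambda_max"


def _nnls_vec(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    # active-set NNLS can cycle on numerically rank-deficient systems;
    # fall back to a bounded trust-region solve in that case
    try:
        x, _ = scipy.optimize.nnls(A, y, maxiter=30 * A.shape[1])
    except RuntimeError:
        res = scipy.optimize.lsq_linear(A, y, bounds=(0.0, np.inf))
        x = np.maximum(res.x, 0.0)
    return x


def nnls(A: KernelMatrix, y: Signal | np.ndarray) -> DistributionFunction:
    """Unregularized NNLS: argmin_{f>=0} ||A f - y||^2."""
    yv = y.values if isinstance(y, Signal) else np.asarray(y, dtype=float)
    if yv.shape != (A.shape[0],):
        raise ValueError("signal length does not match kernel rows")
    return DistributionFunction(_nnls_vec(A.entries, yv), A.t2_grid)


def nnls_tikhonov(A: KernelMatrix, y: Signal | np.ndarray, lam: float) -> DistributionFunction:
    """Tikhonov-regularized NNLS via the augmented system [A; lam*I]."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return nnls(A, y)
    yv = y.values if isinstance(y, Signal) else np.asarray(y, dtype=float)
    m, n = A.shape
    if yv.shape != (m,):
        raise ValueError("signal length does not match kernel rows")
    Aaug = np.vstack([A.entries, lam * np.eye(n)])
    yaug = np.concatenate([yv, np.zeros(n)])
    return DistributionFunction(_nnls_vec(Aaug, yaug), A.t2_grid)


def regularized_family(
    A: KernelMatrix, y: Signal, ladder: LambdaLadder
) -> RegularizedFamily:
    """One Tikhonov-NNLS solve per ladder entry, order preserved."""
    sols = tuple(nnls_tikhonov(A, y, lam) for lam in ladder)
    return RegularizedFamily(ladder=ladder, solutions=sols, signal=y)


def _residual(A: KernelMatrix, y: np.ndarray, lam: float) -> tuple[float, DistributionFunction]:
    f = nnls_tikhonov(A, y, lam)
    return float(np.linalg.norm(A.entries @ f.weights - y)), f


def dp_select_lambda(
    A: KernelMatrix,
    y: Signal,
    cfg: DPConfig,
    bracket_scale: tuple[float, float] = (1e-10, 1e4),
    rtol: float = 1e-3,
    max_iter: int = 200,
) -> DPResult:
    """Discrepancy principle: lam with ||A f_lam - y|| = nu*sqrt(m)*sigma.

    Returns the largest lam whose residual does not exceed the target
    discrepancy level (to relative tolerance ``rtol``), found by bisection
    on log(lam) using the monotone growth of the Tikhonov residual.  The
    bracket is ``bracket_scale`` times the spectral norm of A (the largest
    singular value; for this kernel the small singular values underflow
    double precision and carry no scale information).  If the target is
    unreachable at either end, the boundary lam is returned with a flag
    ("lambda_min" when even the least-regularized fit overshoots the
    target, "lambda_max" when full regularization still underfits it).
    """
    yv = y.values
    m = A.shape[0]
    target = cfg.nu * np.sqrt(m) * cfg.sigma
    level = target * (1.0 + rtol)  # accepted discrepancy level
    scale = float(np.linalg.norm(A.entries, 2))
    lo, hi = bracket_scale[0] * scale, bracket_scale[1] * scale
    r_lo, f_lo = _residual(A, yv, lo)
    if r_lo > level:
        return DPResult(lo, f_lo, r_lo, target, "lambda_min")
    r_hi, f_hi = _residual(A, yv, hi)
    if r_hi <= level:
        return DPResult(hi, f_hi, r_hi, target, "lambda_max")
    # invariant: residual(lam_ok) <= level < residual(lam_bad)
    l_ok, r_ok, f_ok = lo, r_lo, f_lo
    l_bad = hi
    for _ in range(max_iter):
        if l_bad / l_ok < 1.0 + 1e-3 and abs(r_ok - target) <= rtol * target:
            break
        lam = float(np.sqrt(l_ok * l_bad))
        r, f = _residual(A, yv, lam)
        if r <= level:
            l_ok, r_ok, f_ok = lam, r, f
        else:
            l_bad = lam
    return DPResult(l_ok, f_ok, r_ok, target, "ok")


def oracle_lambda_opt(
    A: KernelMatrix,
    y: Signal,
    f_true: DistributionFunction,
    ladder: LambdaLadder,
) -> float:
    """Oracle lambda: ladder entry minimizing ||f_lam - f_true||_2.

    Simulation-only diagnostic (requires the ground truth).  Ties are broken
    toward the larger lambda, preferring more regularization at equal error.
    """
    errs = np.array(
        [np.linalg.norm(nnls_tikhonov(A, y, lam).weights - f_true.weights) for lam in ladder]
    )
    best = errs.min()
    idx = np.nonzero(errs <= best)[0][-1]
    return float(ladder.values[idx])


def simplex_nnls(
    B: np.ndarray,
    n_free: int,
    n_simplex: int,
    ridge: float = 0.0,
) -> np.ndarray:
    """Minimize ||B s||_2 over s >= 0 with the last ``n_simplex`` entries
    summing to one.

    The equality constraint is enforced by appending a heavily weighted
    penalty row (weight 1e6 * ||B||_F) to an NNLS solve, after which the
    simplex block is renormalized so the constraint holds exactly.  A tiny
    ridge (``ridge * I``) can be requested for uniqueness when B'B is
    singular; it is off by default.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[1] != n_free + n_simplex:
        raise ValueError("B must have n_free + n_simplex columns")
    if n_simplex < 1:
        raise ValueError("need at least one simplex variable")
    w = 1e6 * max(float(np.linalg.norm(B)), 1.0)
    crow = np.concatenate([np.zeros(n_free), np.ones(n_simplex)])
    rows = [B, w * crow[None, :]]
    rhs = [np.zeros(B.shape[0]), np.array([w])]
    if ridge > 0:
        k = B.shape[1]
        rows.append(np.sqrt(ridge) * np.eye(k))
        rhs.append(np.zeros(k))
    s = _nnls_vec(np.vstack(rows), np.concatenate(rhs))
    tot = s[n_free:].sum()
    if tot <= 0:  # degenerate; fall back to a uniform feasible point
        s[n_free:] = 1.0 / n_simplex
    else:
        s[n_free:] /= tot
    return s
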