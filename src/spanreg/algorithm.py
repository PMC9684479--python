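"""The SpanReg reconstruction: span-of-regularizations inversion.

Rather than selecting a single Tikhonov regularization weight, SpanReg
returns a non-negative linear combination of differently-regularized NNLS
solutions f_{lambda_j}.  The combination weights are determined by matching
two representations of the unknown density over a Gaussian dictionary whose
atoms have been pushed through the same noisy, regularized inversion:

* offline (per noise level): for each atom g_i and each lambda_j, invert
  A g_i + omega with Tikhonov-NNLS over n_run noise draws and average,
  giving <g_{i,lambda_j}>; per draw, refit each atom on its own inverted
  copies to get the shrinkage coefficients beta_ij, averaged to <beta_ij>.
* online (per signal): expand each f_{lambda_j} over the averaged inverted
  atoms (coefficients x_ij), then solve the stacked constrained problem

      min ||B s||_2,  s >= 0,  sum of the dictionary block of s = 1,

  whose two blocks are the lambda weights alpha and the atom weights c.

The reconstruction is f*_alpha = sum_j alpha_j f_{lambda_j}; the dictionary
side f*_c = sum_i c_i sum_j <beta_ij> <g_{i,lambda_j}> is returned as well
and is essentially equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import KernelMatrix, DistributionFunction, Signal, estimate_noise_sigma
from .dictionary import GaussianDictionary
from .solvers import (
    LambdaLadder,
    RegularizedFamily,
    _nnls_vec,
    nnls_tikhonov,
    regularized_family,
    simplex_nnls,
)

__all__ = [
    "OfflineBasis",
    "SpanRegSystem",
    "SpanRegSolution",
    "build_offline_basis",
    "build_offline_bases_shared",
    "online_x",
    "assemble_system",
    "spanreg_solve",
    "BasisBank",
    "build_basis_bank",
]


@dataclass(frozen=True)
class OfflineBasis:
    """Ensemble-averaged noise-corrupted regularized dictionary.

    ``g_bar[:, i, j]`` is the average Tikhonov-NNLS inversion of atom i at
    ladder entry j; ``beta_bar[i, j]`` the averaged refit coefficient.  In
    the noiseless, unregularized limit beta_bar tends to the identity
    pattern (each atom is its own inversion).
    """

    g_bar: np.ndarray  # (n, M, N)
    beta_bar: np.ndarray  # (M, N)
    sigma: float
    n_run: int
    ladder: LambdaLadder
    dictionary: GaussianDictionary
    seed: int | None

    def __post_init__(self) -> None:
        n, M, N = self.g_bar.shape
        if self.beta_bar.shape != (M, N):
            raise ValueError("beta_bar shape inconsistent with g_bar")
        if N != self.ladder.n or M != self.dictionary.m_members:
            raise ValueError("basis dimensions inconsistent with ladder/dictionary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.g_bar.shape


@dataclass(frozen=True)
class SpanRegSystem:
    """Stacked constrained LS system min ||B s||, s = (alpha; c)."""

    L_alpha: np.ndarray  # (n, MN), columns grouped by lambda
    L_c: np.ndarray  # (n, MN), columns grouped by atom
    x_vec: np.ndarray  # (MN,)
    beta_vec: np.ndarray  # (MN,)
    TT_alpha: np.ndarray  # (MN, N+M)
    TT_c: np.ndarray  # (MN, N+M)
    B: np.ndarray  # (n, N+M)
    n_lambdas: int
    m_members: int


@dataclass(frozen=True)
class SpanRegSolution:
    alpha: np.ndarray  # (N,) lambda weights, >= 0
    c: np.ndarray  # (M,) atom weights on the simplex
    x: np.ndarray  # (M, N) online expansion coefficients
    f_star_alpha: DistributionFunction
    f_star_c: DistributionFunction
    family: RegularizedFamily
    system: SpanRegSystem


def _beta_fit(g_i: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Non-negative refit of one atom on its inverted copies."""
    return _nnls_vec(cols, g_i)


def build_offline_bases_shared(
    A: KernelMatrix,
    G: GaussianDictionary,
    ladder: LambdaLadder,
    sigma: float,
    n_run: int,
    seed: int | None = None,
    sub_ladders: Sequence[Sequence[int]] | None = None,
) -> list[OfflineBasis]:
    """Build one or more offline bases from a single Monte-Carlo sweep.

    For each noise draw k and atom i a single noise vector omega is shared
    across every ladder entry (the same corrupted signal is inverted at each
    lambda).  ``sub_ladders`` selects index subsets of ``ladder``; each
    subset yields its own basis with beta refit restricted to that subset
    (used by the shifted-triplet stability analysis).  The default is one
    basis over the full ladder.
    """
    if n_run < 1:
        raise ValueError("n_run must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sub_ladders is None:
        sub_ladders = [tuple(range(ladder.n))]
    sub_ladders = [tuple(s) for s in sub_ladders]
    n = A.shape[1]
    M = G.m_members
    N = ladder.n
    m = A.shape[0]
    rng = np.random.default_rng(seed)
    g_sum = np.zeros((n, M, N))
    beta_sums = [np.zeros((M, len(s))) for s in sub_ladders]
    clean = A.entries @ G.matrix  # (m, M) noiseless atom signals
    lams = ladder.values
    for _k in range(n_run):
        for i in range(M):
            omega = rng.normal(0.0, sigma, size=m) if sigma > 0 else np.zeros(m)
            y_i = clean[:, i] + omega
            cols = np.empty((n, N))
            for j, lam in enumerate(lams):
                cols[:, j] = nnls_tikhonov(A, y_i, lam).weights
            g_sum[:, i, :] += cols
            for b, sub in enumerate(sub_ladders):
                beta_sums[b][i, :] += _beta_fit(G.matrix[:, i], cols[:, sub])
    g_bar = g_sum / n_run
    out = []
    for b, sub in enumerate(sub_ladders):
        sub_ladder = LambdaLadder(lams[list(sub)])
        out.append(
            OfflineBasis(
                g_bar=np.ascontiguousarray(g_bar[:, :, list(sub)]),
                beta_bar=beta_sums[b] / n_run,
                sigma=sigma,
                n_run=n_run,
                ladder=sub_ladder,
                dictionary=G,
                seed=seed,
            )
        )
    return out


def build_offline_basis(
    A: KernelMatrix,
    G: GaussianDictionary,
    ladder: LambdaLadder,
    sigma: float,
    n_run: int = 50,
    seed: int | None = None,
) -> OfflineBasis:
    """Offline Monte-Carlo basis for one noise level (see module docstring)."""
    return build_offline_bases_shared(A, G, ladder, sigma, n_run, seed)[0]


def online_x(
    family: RegularizedFamily, basis: OfflineBasis, nonneg: bool = True
) -> np.ndarray:
    """Expansion of each f_{lambda_j} over the averaged inverted atoms.

    Returns the M x N coefficient array; column j solves, independently,
    min_{x>=0} ||f_{lambda_j} - sum_i x_ij <g_{i,lambda_j}>||.  Setting
    ``nonneg=False`` uses plain least squares instead.
    """
    if family.ladder.n != basis.ladder.n or not np.allclose(
        family.ladder.values, basis.ladder.values
    ):
        raise ValueError("family and basis were built with different ladders")
    n, M, N = basis.g_bar.shape
    x = np.empty((M, N))
    F = family.as_matrix()
    for j in range(N):
        if nonneg:
            x[:, j] = _nnls_vec(basis.g_bar[:, :, j], F[:, j])
        else:
            x[:, j], *_ = np.linalg.lstsq(basis.g_bar[:, :, j], F[:, j], rcond=None)
    return x


def assemble_system(basis: OfflineBasis, x: np.ndarray) -> SpanRegSystem:
    """Assemble the stacked matrix B of the constrained online problem.

    Column groupings follow the two expansions: L_alpha groups the averaged
    inverted atoms by lambda (atom index fastest), L_c by atom (lambda index
    fastest); x_vec and beta_vec are flattened to match.  The replication
    matrices TT carry the block structure TT_alpha = (I_N (x) 1_M)[I_N 0]
    and TT_c = (I_M (x) 1_N)[0 I_M].
    """
    n, M, N = basis.g_bar.shape
    if x.shape != (M, N):
        raise ValueError("x must be M x N")
    L_alpha = basis.g_bar.transpose(0, 2, 1).reshape(n, N * M)
    L_c = basis.g_bar.reshape(n, M * N)
    x_vec = x.T.reshape(-1)
    beta_vec = basis.beta_bar.reshape(-1)
    ones_M = np.ones((M, 1))
    ones_N = np.ones((N, 1))
    TT_alpha = np.kron(np.eye(N), ones_M) @ np.hstack([np.eye(N), np.zeros((N, M))])
    TT_c = np.kron(np.eye(M), ones_N) @ np.hstack([np.zeros((M, N)), np.eye(M)])
    B = (L_alpha * x_vec) @ TT_alpha - (L_c * beta_vec) @ TT_c
    return SpanRegSystem(
        L_alpha=L_alpha,
        L_c=L_c,
        x_vec=x_vec,
        beta_vec=beta_vec,
        TT_alpha=TT_alpha,
        TT_c=TT_c,
        B=B,
        n_lambdas=N,
        m_members=M,
    )


def spanreg_solve(
    y: Signal,
    A: KernelMatrix,
    basis: OfflineBasis,
    check_sigma: bool = True,
) -> SpanRegSolution:
    """Full online SpanReg reconstruction of one (unit-area-normalized) signal.

    Computes the regularized family, the online expansion x, the stacked
    system, and the constrained weights (alpha, c); returns the primary
    reconstruction f*_alpha = sum_j alpha_j f_{lambda_j} together with the
    dictionary-side f*_c.
    """
    if check_sigma and basis.sigma > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = estimate_noise_sigma(y)
        if not est.tail_not_decayed and est.sigma > 0:
            ratio = est.sigma / basis.sigma
            if ratio > 2.0 or ratio < 0.5:
                warnings.warn(
                    f"estimated signal noise {est.sigma:.3g} differs from the "
                    f"basis noise level {basis.sigma:.3g} by more than 2x",
                    stacklevel=2,
                )
    family = regularized_family(A, y, basis.ladder)
    x = online_x(family, basis)
    system = assemble_system(basis, x)
    N, M = system.n_lambdas, system.m_members
    s = simplex_nnls(system.B, n_free=N, n_simplex=M)
    alpha, c = s[:N], s[N:]
    F = family.as_matrix()
    f_alpha = DistributionFunction(F @ alpha, A.t2_grid)
    f_c_w = np.einsum("i,nij,ij->n", c, basis.g_bar, basis.beta_bar)
    f_c = DistributionFunction(np.maximum(f_c_w, 0.0), A.t2_grid)
    return SpanRegSolution(
        alpha=alpha,
        c=c,
        x=x,
        f_star_alpha=f_alpha,
        f_star_c=f_c,
        family=family,
        system=system,
    )


@dataclass(frozen=True)
class BasisBank:
    """Offline bases keyed by SNR bin, for imaging pipelines.

    ``bin_centers`` are representative SNRs; each basis was built with
    sigma = 1/SNR, the noise level of a unit-amplitude decay at that SNR
    (signals are normalized to unit underlying area before reconstruction).
    """

    bin_centers: np.ndarray
    bases: tuple[OfflineBasis, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.bin_centers):
            raise ValueError("one basis per bin center required")

    def basis_for_bin(self, b: int) -> OfflineBasis:
        return self.bases[b]

    def basis_for_snr(self, snr: float) -> OfflineBasis:
        idx = int(np.argmin(np.abs(np.log(self.bin_centers) - np.log(max(snr, 1e-12)))))
        return self.bases[idx]


def build_basis_bank(
    A: KernelMatrix,
    G: GaussianDictionary,
    ladder: LambdaLadder,
    bin_centers: np.ndarray,
    n_run: int = 50,
    seed: int | None = None,
) -> BasisBank:
    """One offline basis per SNR bin center (sigma = 1/SNR per bin)."""
    bases = []
    for k, snr in enumerate(bin_centers):
        sub_seed = None if seed is None else (seed + 7919 * k) % (2**31 - 1)
        bases.append(
            build_offline_basis(A, G, ladder, sigma=1.0 / snr, n_run=n_run, seed=sub_seed)
        )
    return BasisBank(np.asarray(bin_centers, dtype=float), tuple(bases))
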