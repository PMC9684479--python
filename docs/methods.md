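# Methods

## Forward model and discretization

The package treats multi-echo relaxometry decays as discretized Laplace
transforms `y = A f + ω` with kernel entries
`A[i, j] = exp(−t_i / T2_j) · ΔT2`.  The quadrature weight ΔT2 is folded
into the kernel, so the unknown `f` is a *density* (units 1/ms) and all
areas are discrete sums `Σ f · ΔT2`.  Both grids are linearly spaced by
default: the standard simulation configuration is n = 200 T2 points at
1 ms spacing on [1, 200] ms and m = 150 measurement times on
[0.3, 400] ms; whether the sampling times should instead be log-spaced is
not determined by the source problem, and linear spacing is the
assumption used throughout.  The spin-echo variant uses TE_i = i × TE
(default TE = 11.3 ms, 32 echoes) with no t = 0 sample.

Noise is additive i.i.d. zero-mean Gaussian, the high-SNR approximation
to magnitude-image Rician noise; SNR is defined as max|y| / RMS(ω).
Noise can be estimated from the decayed signal tail (default: sample SD
of the last 20% of points after mean removal); the estimate is flagged
when the tail mean exceeds five sample SDs, the signature of incomplete
decay.  Tail estimates are biased upward whenever slow components have
not decayed by the last echo, which is why the imaging pipeline accepts a
known per-pixel SNR map as an alternative.

## Solvers

All inversions enforce f ≥ 0.  Tikhonov-NNLS is solved exactly as NNLS on
the augmented system [A; λI] vs [y; 0] (scipy's active-set NNLS, with a
bounded trust-region fallback for the rare numerically rank-deficient
case where the active-set method cycles).

The discrepancy-principle selector returns the largest λ whose residual
does not exceed ν·√m·σ (relative tolerance 1e-3), by bisection on log λ
using the monotone growth of the Tikhonov residual.  The safety factor
defaults to ν = 1.05.  The bisection bracket is [1e-10, 1e4] times the
spectral norm of A: the *median* singular value would be the natural
scale for a well-conditioned operator, but this kernel's spectrum decays
below machine precision (cond(A) ≳ 1e17), so only the largest singular
value carries usable scale information.  When the target residual is
unreachable — noise grossly over- or under-estimated — the boundary λ is
returned with a `lambda_min` / `lambda_max` flag.  Returning the largest
admissible λ (rather than any λ whose residual crosses the target) makes
the selector robust to realizations where the minimum attainable residual
sits just above the target: those would otherwise degenerate to the
unregularized, maximally noisy solution.

The simplex-constrained stacked problem min ‖B s‖, s ≥ 0, Σc = 1 is
solved as a penalty-row NNLS: a row w·(0…0, 1…1) with w = 1e6·‖B‖_F and
right-hand side w is appended, after which the simplex block is
renormalized so the equality holds exactly.  At this weight the
perturbation to the minimizer is far below solver tolerance; the test
suite cross-checks the result against an SLSQP solve with the exact
equality constraint (agreement to 1e-4) and against dense barycentric
grid searches.  An optional ridge term is available for uniqueness when
BᵀB is singular; it is off by default.  The oracle λ (simulation-only)
scans the ladder for the smallest ‖f_λ − f_true‖ and breaks ties toward
the larger λ, preferring more regularization at equal error.

## The Gaussian dictionary

The density is represented over unit-area Gaussian atoms.  The default
dictionary has three families with means equally spaced across the full
T2 range, endpoints included (spacing (τ_U − τ_L)/(count − 1)): 160 atoms
of SD 2 ms, 40 of SD 3 ms, 20 of SD 4 ms (M = 220).  Each column is the
Gaussian density evaluated on the grid and renormalized to unit discrete
area, so edge-truncated atoms remain probability densities and the
simplex constraint Σc = 1 stays meaningful.  Atoms narrower than half the
grid spacing trigger an under-resolution warning.

## SpanReg

Offline, for one noise level σ: for every noise draw k and atom i, a
single noise vector ω is drawn and the corrupted atom signal
A g_i + ω is inverted at *every* ladder entry (the draw is shared across
λ, mirroring how one physical noise realization enters all regularized
inversions of the same data).  The ensemble averages ⟨g_{i,λ_j}⟩ over
n_run draws form the basis; per draw, each atom is refit non-negatively
on its own inverted copies, and the refit coefficients are averaged to
⟨β_ij⟩ (fit-then-average, matching the definition of the ensemble-mean
coefficient).  In the σ → 0, λ → 0 limit the inverted atoms return
themselves and β collapses to the identity pattern — this limit is
asserted in the tests on a configuration whose noiseless inversion floor
is below the tolerance; on the severely ill-conditioned default kernel
the floor is ~3e-4 in absolute density units.

Online, the regularized family of the (unit-area-normalized) signal is
computed, each f_{λ_j} is expanded non-negatively over the bin's averaged
inverted atoms (x_ij; the unconstrained expansion is available as an
option but degrades resolution markedly), the stacked system B is
assembled from the two groupings of ⟨g_{i,λ_j}⟩, and the simplex solver
yields (α, c).  The primary reconstruction is f*_α = Σ_j α_j f_{λ_j};
the dictionary-side f*_c is also returned and is essentially equivalent.
The offline basis is immutable; reconstructions share no state.

n_run is a pure Monte-Carlo accuracy knob.  The library default is 50,
which stabilizes ⟨g⟩ and ⟨β⟩ at the SNR range of interest while keeping
an offline build on the full 220-atom dictionary to minutes on one CPU;
the test suite and the acceptance script use n_run = 10, the scale at
which the two-peak resolution experiment is specified.

For imaging, a `BasisBank` holds one basis per SNR bin (default 18
geometrically spaced bins on [10, 800] — noise impact is multiplicative,
hence log spacing).  Bank bases use σ = 1/SNR, the noise level of a
unit-amplitude decay, consistent with the unit-area normalization applied
to every pixel before reconstruction.

## Simulation study

Phantoms are sums of two Gaussians; the standard grid crosses
σ1 ∈ {2, 2.75, 3.5, 4.25, 5} ms (σ2 = 3σ1) with peak-separation ratios
RPS ∈ {1, 1.75, 2.5, 3.25, 4} at μ1 = 35 ms (the resolution experiments
use μ1 = 30 ms); no phantom component coincides with a dictionary atom.
As written, the two-Gaussian sum integrates to 2; because the
reconstruction treats densities as probability distributions, phantoms
are normalized to unit area before synthesis.  The error metric
‖f_rec − f_true‖₂/‖f_true‖₂ is scale-invariant, so comparisons are
unaffected.

Peak resolution is counted as the number of local maxima with prominence
at least 5% of the global maximum and at least 3 grid points of
separation; both thresholds are package conventions (configurable), not
derived quantities.  Comparison tables average relative errors over a
small number of noise seeds per phantom (default 3), with per-cell seeds
derived from a master seed plus the cell index.

The stability analysis measures sensitivity to misplacing the
regularization anchor: the oracle λ_opt is found on the standard ladder,
and the comparison set is S = λ_opt·2^e, e = −4…5.  The Tikhonov branch
reports ‖f_{λ_opt} − f_{λ_opt/2^j}‖.  The reference formulation of the
SpanReg branch is self-referential; here each anchor λ_a contributes the
reconstruction obtained by running SpanReg restricted to the 3-λ ladder
(λ_a/2, λ_a, 2λ_a), with all triplet bases drawn from one shared
Monte-Carlo sweep so that differences between triplets reflect the ladder
shift, not sampling jitter.  Empirically this construction is markedly
more stable than single-λ Tikhonov on the under-regularized side of
λ_opt and comparable (not always better) on the over-regularized side;
see the known-limitations note below.

## MWF imaging

Spin-echo data lack a t = 0 sample, so per pixel the TE = 0 amplitude is
estimated as ‖f_LS‖₁·ΔT2 from an unregularized NNLS fit and the decay is
divided by it, normalizing the underlying density to unit area without
introducing regularization bias.  The myelin water fraction is the
fraction of the density's area within the [6, 40] ms window (inclusive,
configurable); computing it as a fraction of total area makes it robust
to imperfect normalization.  Maps are compared with the scaled absolute
difference SAD(A, B) = Σ|A−B| / Σ|A| over valid pixels.  Per-pixel work
is independent of traversal order.

The synthetic phantom emulates the acquisition geometry (32 echoes at
11.3 ms) with three horizontal tissue bands of two-to-three-component
Gaussian densities — a short-T2 pool inside the myelin window (15–25% of
area, matching white-matter-like fractions) plus longer pools — and a
per-pixel SNR field spanning [10, 800].  It does not emulate spatial
correlation of noise, partial-volume mixing at band boundaries, Rician
bias at low SNR, or B1/stimulated-echo effects; passing tests therefore
demonstrate correct behavior of the inversion chain under the stated
noise model, not scanner-grade accuracy.

## Problem sizes in the shipped tests

The default test run builds one offline basis at the full study
conditions (M = 220, N = 16) with n_run = 10, shares it across the
simulation-study tests, and uses reduced dictionaries (M ≤ 80) and small
image stacks (10×10) for algebraic and imaging checks; the acceptance
script uses the full conditions with n_run = 10.

## Known limitations

* The noiseless, tiny-λ regime of the default kernel is numerically
  degenerate: NNLS returns one of many near-equivalent solutions, so
  noiseless reconstructions are exactly reproducible only within one
  BLAS/LAPACK build.
* The strict stability ordering (SpanReg triplet differences below
  Tikhonov differences at *every* shift) does not reliably hold on the
  over-regularized side under this package's triplet construction; the
  advantage on the under-regularized side — where Tikhonov is least
  stable — is robust.
* SpanReg accuracy is floored by the dictionary's simplex-representation
  error; densities far outside the atom families (very broad, very
  narrow, or near the grid edges) are reconstructed at reduced fidelity.
* Rician noise, complex-valued data, and stimulated-echo corrections to
  the exponential kernel are out of scope.
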