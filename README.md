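# spanreg

Span-of-regularizations (SpanReg) inversion for multi-exponential T2
relaxometry, with an application to myelin-water-fraction (MWF) mapping of
the brain.

## The problem

A multi-echo magnetic-resonance relaxometry signal is a noisy Laplace
transform of the transverse-relaxation-time density f(T2):

    y(t_i) = Σ_j exp(−t_i / T2_j) · f(T2_j) · ΔT2 + ω_i,    f ≥ 0,

or `y = A f + ω`.  Recovering f is a discretized inverse Laplace
transform — severely ill-posed: the kernel's condition number on the
standard 150×200 configuration exceeds 1e15.  The classical remedy is
Tikhonov-regularized non-negative least squares,

    f_λ = argmin_{f ≥ 0} ‖A f − y‖² + λ²‖f‖²,

with λ chosen by a selection rule such as the Morozov discrepancy
principle (DP), which picks λ so the fit residual matches the expected
noise norm ν·√m·σ.  Any single λ trades resolution against stability and
discards the rest of the regularization path.

## The method

SpanReg keeps the whole path.  The reconstruction is a non-negative
combination of differently-regularized solutions,

    f* = Σ_j α_j f_{λ_j},

over a ladder of N log-spaced λ's.  The weights α are determined by
matching two representations of the unknown density over a dictionary of
M unit-area Gaussian atoms g_i whose *noise-corrupted regularized
inversions* ⟨g_{i,λ_j}⟩ = ⟨A⁻¹_{λ_j}(A g_i + ω)⟩ are precomputed offline
for the data's noise level (ensemble average over n_run noise draws,
together with refit coefficients ⟨β_ij⟩ of each atom on its own inverted
copies).  Online, each f_{λ_j} is expanded over the inverted atoms
(coefficients x_ij) and the stacked constrained problem

    min ‖B s‖₂   s.t.  s = (α; c) ≥ 0,  Σ_i c_i = 1,

is solved, where B balances the λ-side expansion against the
dictionary-side expansion Σ_i c_i Σ_j ⟨β_ij⟩⟨g_{i,λ_j}⟩.  The stacked
matrix B is orders of magnitude better conditioned than A itself.  The
result combines the stability of strongly regularized solutions with the
resolution of weakly regularized ones.

## Worked example

Recover a hard, closely spaced two-Gaussian T2 density (components at
30 ms and 50 ms, SDs 3 and 5 ms) from decays at SNR 500, and compare
against the discrepancy principle:

```python
import numpy as np
import spanreg as sr

grid   = sr.make_t2_grid(200, 1, 200)          # 1 ms steps on [1, 200] ms
times  = sr.make_time_grid(150, 0.3, 400)      # 150 sampling times
A      = sr.build_kernel(times, grid)
G      = sr.default_dictionary(grid)           # 220 Gaussian atoms
ladder = sr.LambdaLadder.log_spaced(16, 1e-6, 10)

# offline (once per noise level): noise-corrupted regularized dictionary
basis = sr.build_offline_basis(A, G, ladder, sigma=1/500, n_run=10, seed=1)

# online: reconstruct 10 independent noisy realizations
spec = sr.PhantomSpec(mu1=30, mu2=50, sigma1=3, sigma2=5)
table = sr.resolution_experiment(spec, A, snr=500, basis=basis,
                                 n_realizations=10, seed=0)
print("SpanReg resolves two peaks in",
      int((table.peaks_spanreg == 2).sum()), "of 10 runs")
print("DP resolves two peaks in",
      int((table.peaks_dp == 2).sum()), "of 10 runs")
print("mean relative error: SpanReg %.3f vs DP %.3f"
      % (table.eps_spanreg.mean(), table.eps_dp.mean()))
```

Output:

```
SpanReg resolves two peaks in 8 of 10 runs
DP resolves two peaks in 1 of 10 runs
mean relative error: SpanReg 0.471 vs DP 0.754
```

The two components are separated by only a factor 1.67 in T2; the
discrepancy principle almost always merges them into a single broad peak,
while SpanReg resolves both in most noise realizations and with lower L2
error.

A command-line interface mirrors the library
(`spanreg offline / reconstruct / simulate / phantom / map`); see
`spanreg --help`.

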