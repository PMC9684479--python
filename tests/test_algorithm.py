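"""Offline basis construction and the online SpanReg reconstruction."""

import warnings

import numpy as np
import pytest

import spanreg as sr
from spanreg.algorithm import (
    assemble_system,
    build_offline_bases_shared,
    build_offline_basis,
    online_x,
)


@pytest.fixture(scope="module")
def tiny_setup():
    """Small well-conditioned instance for exact algebraic checks."""
    grid = sr.make_t2_grid(50, 5.0, 120.0)
    times = sr.make_time_grid(80, 0.0, 500.0)
    A = sr.build_kernel(times, grid)
    G = sr.build_dictionary(
        grid, [sr.GaussianFamilySpec(6, 10.0), sr.GaussianFamilySpec(4, 14.0)]
    )
    ladder = sr.LambdaLadder(np.array([1e-6, 1e-4, 1e-2]))
    return grid, A, G, ladder


@pytest.fixture(scope="module")
def tiny_basis(tiny_setup):
    _grid, A, G, ladder = tiny_setup
    return build_offline_basis(A, G, ladder, sigma=1e-3, n_run=5, seed=2)


class TestOfflineBasis:
    def test_shapes_and_nonnegativity(self, tiny_basis, tiny_setup):
        grid, _A, G, ladder = tiny_setup
        assert tiny_basis.g_bar.shape == (grid.n, G.m_members, ladder.n)
        assert tiny_basis.beta_bar.shape == (G.m_members, ladder.n)
        assert np.all(tiny_basis.g_bar >= 0)
        assert np.all(tiny_basis.beta_bar >= 0)

    def test_deterministic_given_seed(self, tiny_setup):
        _grid, A, G, ladder = tiny_setup
        a = build_offline_basis(A, G, ladder, sigma=1e-3, n_run=3, seed=9)
        b = build_offline_basis(A, G, ladder, sigma=1e-3, n_run=3, seed=9)
        assert np.array_equal(a.g_bar, b.g_bar)
        assert np.array_equal(a.beta_bar, b.beta_bar)

    def test_noiseless_unregularized_limit(self):
        """With no noise and vanishing regularization the inverted atoms
        return themselves and the refit coefficients are the identity."""
        grid = sr.make_t2_grid(40, 5.0, 120.0)
        A = sr.build_kernel(sr.make_time_grid(60, 0.0, 500.0), grid)
        G = sr.build_dictionary(grid, [sr.GaussianFamilySpec(5, 14.0)])
        b = build_offline_basis(
            A, G, sr.LambdaLadder(np.array([1e-12])), sigma=0.0, n_run=1, seed=0
        )
        assert np.abs(b.g_bar[:, :, 0] - G.matrix).max() < 1e-4
        assert np.abs(b.beta_bar - 1.0).max() < 1e-3

    def test_ensemble_variance_scales_inversely_with_n_run(self):
        """Monte-Carlo averaging: variance of <g> entries ~ 1/n_run."""
        grid = sr.make_t2_grid(30, 5.0, 120.0)
        times = sr.make_time_grid(40, 0.0, 500.0)
        A = sr.build_kernel(times, grid)
        G = sr.build_dictionary(grid, [sr.GaussianFamilySpec(4, 12.0)])
        ladder = sr.LambdaLadder(np.array([1e-3]))
        n_runs = [4, 16, 64]
        variances = []
        for nr in n_runs:
            reps = [
                build_offline_basis(A, G, ladder, sigma=5e-3, n_run=nr, seed=100 + r).g_bar
                for r in range(6)
            ]
            variances.append(np.var(np.stack(reps), axis=0).mean())
        slope = np.polyfit(np.log(n_runs), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.35)

    def test_invalid_n_run(self, tiny_setup):
        _grid, A, G, ladder = tiny_setup
        with pytest.raises(ValueError):
            build_offline_basis(A, G, ladder, sigma=1e-3, n_run=0)

    def test_sub_ladders_share_sweep(self, tiny_setup):
        _grid, A, G, ladder = tiny_setup
        full, sub = build_offline_bases_shared(
            A, G, ladder, sigma=1e-3, n_run=3, seed=4,
            sub_ladders=[(0, 1, 2), (0, 1)],
        )
        assert np.array_equal(sub.g_bar, full.g_bar[:, :, :2])
        assert sub.ladder.n == 2


class TestOnlineX:
    def test_exact_member_zero_residual(self, tiny_basis, tiny_setup):
        _grid, A, _G, ladder = tiny_setup
        M, N = tiny_basis.beta_bar.shape
        fam = sr.RegularizedFamily(
            ladder=ladder,
            solutions=tuple(
                sr.DistributionFunction(tiny_basis.g_bar[:, 5, j], tiny_basis.dictionary.grid)
                for j in range(N)
            ),
            signal=sr.Signal(np.zeros(A.shape[0]), A.time_grid),
        )
        x = online_x(fam, tiny_basis)
        for j in range(N):
            resid = np.linalg.norm(
                tiny_basis.g_bar[:, :, j] @ x[:, j] - tiny_basis.g_bar[:, 5, j]
            )
            assert resid <= 1e-8

    def test_zero_family_zero_x(self, tiny_basis, tiny_setup):
        grid, A, _G, ladder = tiny_setup
        fam = sr.RegularizedFamily(
            ladder=ladder,
            solutions=tuple(
                sr.DistributionFunction(np.zeros(grid.n), grid) for _ in range(ladder.n)
            ),
            signal=sr.Signal(np.zeros(A.shape[0]), A.time_grid),
        )
        assert np.all(online_x(fam, tiny_basis) == 0)

    def test_matches_grid_search_oracle(self):
        """Three-atom toy: non-negative expansion matches a dense scan."""
        grid = sr.make_t2_grid(40, 5.0, 120.0)
        times = sr.make_time_grid(50, 0.0, 500.0)
        A = sr.build_kernel(times, grid)
        G = sr.build_dictionary(grid, [sr.GaussianFamilySpec(3, 12.0)])
        ladder = sr.LambdaLadder(np.array([1e-3]))
        basis = build_offline_basis(A, G, ladder, sigma=1e-3, n_run=4, seed=3)
        target = 0.5 * G.matrix[:, 0] + 0.4 * G.matrix[:, 2]
        fam = sr.RegularizedFamily(
            ladder=ladder,
            solutions=(sr.DistributionFunction(target, grid),),
            signal=sr.Signal(np.zeros(A.shape[0]), A.time_grid),
        )
        x = online_x(fam, basis)[:, 0]
        g = np.arange(0, 1.0001, 0.01)
        best = np.inf
        D = basis.g_bar[:, :, 0]
        for x1 in g:
            for x2 in g:
                r = target[:, None] - np.outer(D[:, 0], np.full_like(g, x1)) \
                    - np.outer(D[:, 1], np.full_like(g, x2)) - np.outer(D[:, 2], g)
                best = min(best, np.linalg.norm(r, axis=0).min())
        assert np.linalg.norm(D @ x - target) <= best + 1e-4

    def test_ladder_mismatch_rejected(self, tiny_basis, tiny_setup):
        grid, A, _G, _ladder = tiny_setup
        other = sr.LambdaLadder(np.array([1e-5, 1e-3, 1e-1]))
        fam = sr.RegularizedFamily(
            ladder=other,
            solutions=tuple(
                sr.DistributionFunction(np.zeros(grid.n), grid) for _ in range(3)
            ),
            signal=sr.Signal(np.zeros(A.shape[0]), A.time_grid),
        )
        with pytest.raises(ValueError):
            online_x(fam, tiny_basis)


class TestAssembleSystem:
    def test_kronecker_replication(self, tiny_basis):
        M, N = tiny_basis.beta_bar.shape
        rng = np.random.default_rng(0)
        x = rng.random((M, N))
        sys_ = assemble_system(tiny_basis, x)
        s = rng.random(N + M)
        assert np.allclose(sys_.TT_alpha @ s, np.kron(s[:N], np.ones(M)))
        assert np.allclose(sys_.TT_c @ s, np.kron(s[N:], np.ones(N)))
        assert sys_.TT_alpha.shape == (M * N, N + M)
        assert sys_.TT_c.shape == (M * N, N + M)

    def test_stacked_matrix_matches_direct_sums(self, tiny_basis):
        """B s equals the difference of the two expansion sums computed
        directly, for random s."""
        M, N = tiny_basis.beta_bar.shape
        rng = np.random.default_rng(1)
        x = rng.random((M, N))
        sys_ = assemble_system(tiny_basis, x)
        for _ in range(3):
            s = rng.random(N + M)
            alpha, c = s[:N], s[N:]
            f_alpha = sum(
                alpha[j] * (tiny_basis.g_bar[:, :, j] @ x[:, j]) for j in range(N)
            )
            f_c = sum(
                c[i] * (tiny_basis.g_bar[:, i, :] @ tiny_basis.beta_bar[i, :])
                for i in range(M)
            )
            assert np.allclose(sys_.B @ s, f_alpha - f_c, atol=1e-12)

    def test_invariant_factorization(self, tiny_basis):
        M, N = tiny_basis.beta_bar.shape
        x = np.random.default_rng(2).random((M, N))
        sys_ = assemble_system(tiny_basis, x)
        B_ref = (
            sys_.L_alpha @ np.diag(sys_.x_vec) @ sys_.TT_alpha
            - sys_.L_c @ np.diag(sys_.beta_vec) @ sys_.TT_c
        )
        assert np.allclose(sys_.B, B_ref, atol=1e-14)


class TestSpanRegSolve:
    def test_constraints_hold(self, tiny_setup, tiny_basis):
        _grid, A, G, _ladder = tiny_setup
        f = sr.two_gaussian_df(sr.PhantomSpec(30, 60, 5, 8), A.t2_grid)
        y = sr.add_noise(sr.synthesize_signal(A, f), snr=500, rng=np.random.default_rng(3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = sr.spanreg_solve(y, A, tiny_basis)
        assert np.all(sol.alpha >= 0)
        assert np.all(sol.c >= 0)
        assert sol.c.sum() == pytest.approx(1.0, abs=1e-8)
        # f*_alpha is exactly the alpha-combination of the family
        F = sol.family.as_matrix()
        assert np.allclose(sol.f_star_alpha.weights, F @ sol.alpha, atol=1e-14)

    def test_deterministic_and_stateless(self, tiny_setup, tiny_basis):
        _grid, A, _G, _ladder = tiny_setup
        f = sr.two_gaussian_df(sr.PhantomSpec(30, 60, 5, 8), A.t2_grid)
        y1 = sr.add_noise(sr.synthesize_signal(A, f), snr=500, rng=np.random.default_rng(4))
        y2 = sr.add_noise(sr.synthesize_signal(A, f), snr=500, rng=np.random.default_rng(5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1 = sr.spanreg_solve(y1, A, tiny_basis).f_star_alpha.weights
            _ = sr.spanreg_solve(y2, A, tiny_basis)
            a2 = sr.spanreg_solve(y1, A, tiny_basis).f_star_alpha.weights
        assert np.array_equal(a1, a2)

    def test_sigma_mismatch_warns(self, tiny_setup, tiny_basis):
        _grid, A, _G, _ladder = tiny_setup
        # decayed tail with noise 100x the basis sigma
        f = sr.evaluate_gaussian(20.0, 5.0, A.t2_grid).normalized()
        y = sr.add_noise(
            sr.synthesize_signal(A, f),
            noise=sr.NoiseModel(sigma=100 * tiny_basis.sigma, seed=0),
        )
        with pytest.warns(UserWarning, match="differs from the basis"):
            sr.spanreg_solve(y, A, tiny_basis)

    def test_member_self_consistency(self, tiny_setup):
        """Noiseless data from a dictionary atom with a near-zero-noise
        basis concentrates c on that atom."""
        _grid, A, G, _ = tiny_setup
        ladder = sr.LambdaLadder(np.array([1e-8, 1e-6, 1e-4]))
        basis = build_offline_basis(A, G, ladder, sigma=0.0, n_run=1, seed=0)
        f_true = G.column(3)
        y = sr.synthesize_signal(A, f_true)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = sr.spanreg_solve(y, A, basis)
        assert sol.c.argmax() == 3
        assert sol.c.max() >= 0.9
        assert sr.relative_error(sol.f_star_alpha, f_true) <= 0.05


class TestBasisBank:
    def test_nearest_log_lookup(self, tiny_setup):
        _grid, A, G, ladder = tiny_setup
        centers = np.array([10.0, 100.0, 800.0])
        bank = sr.build_basis_bank(A, G, ladder, centers, n_run=1, seed=0)
        assert bank.basis_for_snr(12.0) is bank.bases[0]
        assert bank.basis_for_snr(280.0) is bank.bases[1]
        assert bank.basis_for_snr(5000.0) is bank.bases[2]
        for snr, b in zip(centers, bank.bases):
            assert b.sigma == pytest.approx(1.0 / snr)


class TestConditioning:
    def test_stacked_system_far_better_conditioned_than_kernel(
        self, sim_kernel, sim_grid, study_basis
    ):
        """The online stacked matrix B is at least ten orders of magnitude
        better conditioned than the exponential kernel itself."""
        f = sr.two_gaussian_df(sr.PhantomSpec(35, 87.5, 3.5, 10.5), sim_grid)
        y = sr.add_noise(
            sr.synthesize_signal(sim_kernel, f), snr=500,
            rng=np.random.default_rng(0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = sr.spanreg_solve(y, sim_kernel, study_basis)
        sv_A = np.linalg.svd(sim_kernel.entries, compute_uv=False)
        sv_B = np.linalg.svd(sol.system.B, compute_uv=False)
        cond_A = sv_A[0] / sv_A[-1]
        cond_B = sv_B[0] / sv_B[-1]
        assert cond_B <= 1e-10 * cond_A
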