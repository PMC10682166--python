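"""Dispersion relations, Routh-Hurwitz reduction and Turing scans."""

import numpy as np
import pytest

import savanna_patterns as sp
from savanna_patterns.dispersion import (
    forest_eigenvalue_sl4,
    reduced_block_sl4,
    sl4_matrix,
)
from savanna_patterns.nonspatial import HomogeneousState


def stable_interior(p):
    return [e for e in sp.find_equilibria(p) if e.stable and not e.is_all_grass]


def random_kernel_triple(rng):
    makers = (sp.make_gaussian, sp.make_laplace, sp.make_uniform)
    def draw():
        return makers[rng.integers(3)](float(rng.uniform(0.01, 0.5)))
    return {"w": draw(), "JF": draw(), "JT": draw(), "R": draw()}


class TestCoefficients:
    def test_sign_pattern_at_forest_root(self, gf_params):
        eq = min(stable_interior(gf_params), key=lambda e: e.G)
        A, B, C, D = sp.coefficients_ABCD(eq.G, gf_params)
        assert A >= 0 and B < 0 and C > 0 and D < 0

    def test_heaviside_A_is_zero(self):
        p = sp.default_params("RL-GF", heaviside=True, alpha=2.15, r=1.0)
        eq = stable_interior(p)[0]
        A, *_ = sp.coefficients_ABCD(eq.G, p)
        assert A == 0.0

    def test_sum_is_ode_eigenvalue(self, gf_params):
        for e in sp.find_equilibria(gf_params):
            if e.is_all_grass:
                continue
            s = sum(sp.coefficients_ABCD(e.G, gf_params))
            j = sp.jacobian(e.state, gf_params, warn=False)[0, 0]
            assert s == pytest.approx(j, abs=1e-12)
            assert (s < 0) == e.stable

    def test_boundary_state_rejected(self, gf_params):
        with pytest.raises(ValueError):
            sp.coefficients_ABCD(1.0, gf_params)


class TestScalarDispersion:
    def test_zero_mode_value(self, gf_params, top_row_kernels):
        eq = stable_interior(gf_params)[0]
        lam0 = sp.dispersion_gf(eq.G, gf_params, top_row_kernels, 0.0)
        assert lam0 == pytest.approx(sum(sp.coefficients_ABCD(eq.G, gf_params)))

    def test_even_in_xi_and_limit_D(self, gf_params, top_row_kernels):
        eq = stable_interior(gf_params)[0]
        lam_p = sp.dispersion_gf(eq.G, gf_params, top_row_kernels, 17.0)
        lam_m = sp.dispersion_gf(eq.G, gf_params, top_row_kernels, -17.0)
        assert lam_p == lam_m
        D = sp.coefficients_ABCD(eq.G, gf_params)[3]
        far = sp.dispersion_gf(eq.G, gf_params, top_row_kernels, 1e3)
        assert far == pytest.approx(D, abs=1e-10)
        assert far < 0

    def test_all_grass_sup_at_zero(self, top_row_kernels):
        """All-grass dispersion is -phi(1) + alpha JF_hat, maximal at xi=0."""
        p = sp.default_params("RL-GF", alpha=0.7, r=0.9)  # all-grass stable
        xi = np.linspace(0, 300, 2001)
        lam = sp.dispersion_all_grass(p, top_row_kernels, xi)
        assert lam[0] == pytest.approx(p.alpha - p.phi(1.0))
        assert np.argmax(lam) == 0
        assert np.max(lam) < 0

    def test_dense_matrix_oracle(self):
        """Eigenvalues of the discretized linearization equal lambda_xi.

        Brute-force check: the dense Jacobian of the spatial scalar model at
        a homogeneous equilibrium on a 64-point periodic box is a sum of
        circulants, so its spectrum must sample the dispersion relation at
        the box's integer wavenumbers.
        """
        p = sp.default_params("RL-GF", alpha=2.15, r=1.0)
        kernels = sp.gaussian_kernels(sigma_w=0.3, sigma_f=0.35, sigma_r=0.5)
        grid = sp.SpatialGrid(n=64)
        ops = sp.GFOperators(kernels, grid)
        eq = stable_interior(p)[0]
        g = np.full(grid.n, eq.G)
        ev = np.sort(np.linalg.eigvals(sp.steady_jacobian(g, p.alpha, p, ops)).real)
        modes = np.abs(np.fft.fftfreq(grid.n, d=1 / grid.n))  # 0,1,...,32,...
        lam = np.sort(np.real(sp.dispersion_gf(eq.G, p, kernels, modes)))
        assert np.max(np.abs(ev - lam)) < 1e-8


class TestNecessaryCondition:
    def test_kernel_free_and_heaviside_reduction(self):
        p = sp.default_params("RL-GF", heaviside=True, alpha=2.15, r=1.0)
        ns, _ = sp.necessary_condition_N(p)
        for e, n in zip(stable_interior(p), ns):
            A, B, C, D = sp.coefficients_ABCD(e.G, p)
            assert A == 0.0
            assert n == pytest.approx(C + D)

    def test_no_instability_where_N_nonpositive(self, rng):
        """N <= 0 for every stable branch implies a negative dispersion max
        for any positive-definite kernel triple (50 random draws)."""
        candidates = [(2.0, 0.95), (1.5, 0.9), (3.0, 0.98), (2.5, 0.6)]
        checked = 0
        for alpha, r in candidates:
            p = sp.default_params("RL-GF", alpha=alpha, r=r)
            ns, mx = sp.necessary_condition_N(p)
            if mx is None or mx > 0:
                continue
            for _ in range(50):
                kern = random_kernel_triple(rng)
                for e in stable_interior(p):
                    assert sp.max_dispersion_gf(e.G, p, kern) < 0
                checked += 1
        assert checked >= 50

    def test_dispersion_bounded_by_N(self, rng, gf_params):
        """max lambda_xi <= A + C + D for positive-definite kernels."""
        for e in stable_interior(gf_params):
            A, B, C, D = sp.coefficients_ABCD(e.G, gf_params)
            for _ in range(20):
                kern = random_kernel_triple(rng)
                if any(sp.check_hypotheses(k).min_fourier < 0 for k in kern.values()):
                    continue  # uniform kernels are not positive definite
                assert sp.max_dispersion_gf(e.G, gf_params, kern) <= A + C + D + 1e-10


class TestFourTypeDispersion:
    def test_zero_mode_matches_substituted_jacobian(self):
        p = sp.default_params("SL4", heaviside=True, alpha=0.2, beta=1.0)
        eq = [e for e in sp.find_equilibria(p) if e.stable and e.state.T > 0.1][0]
        kern = sp.gaussian_kernels(0.05, 0.1, 0.4)
        ev0 = np.sort_complex(sp.dispersion_sl4(eq.state, p, kern, 0.0))
        ev_j = np.sort_complex(np.linalg.eigvals(sp.jacobian4(eq.state, p)))
        assert np.allclose(ev0, ev_j, atol=1e-12)

    def test_factored_spectrum_equals_full_matrix(self, rng):
        """Forest eigenvalue + 3x3 block = full 4x4 spectrum (100 draws)."""
        p = sp.default_params("RL-SL4", heaviside=True, alpha=2.0, beta=2.0,
                              r=0.84)
        eqs = [e for e in sp.find_equilibria(p) if not e.is_all_grass]
        kern = sp.gaussian_kernels(0.05, 0.1, 0.4, sigma_t=0.2)
        for _ in range(100):
            eq = eqs[rng.integers(len(eqs))]
            xi = float(rng.uniform(0, 40))
            full = np.sort_complex(sp.dispersion_sl4(eq.state, p, kern, xi))
            lam_f = forest_eigenvalue_sl4(eq.state, p, kern, xi)
            jt_hat = sp.fourier_transform(kern["JT"], xi)
            block = np.linalg.eigvals(reduced_block_sl4(eq.state, p, jt_hat))
            fact = np.sort_complex(np.append(block, lam_f))
            assert np.max(np.abs(full - fact)) < 1e-10

    def test_forest_eigenvalue_sl4_sup_at_zero(self):
        """SL4 forest spectrum alpha(1-F)JF_hat - alpha F - phi(G): sup at 0."""
        p = sp.default_params("SL4", heaviside=True, alpha=0.2, beta=1.0)
        eq = [e for e in sp.find_equilibria(p) if e.stable][0]
        kern = {"JF": sp.make_gaussian(0.1)}
        xi = np.linspace(0, 100, 501)
        lam = forest_eigenvalue_sl4(eq.state, p, kern, xi)
        f, g = eq.state.F, eq.state.G
        assert lam[0] == pytest.approx(p.alpha * (1 - f) - p.alpha * f - p.phi(g))
        assert np.argmax(lam) == 0

    def test_proposition_no_spatial_instability_sl4(self, rng):
        """ODE-stable four-type equilibria stay stable spatially.

        Heaviside fire responses and 25 random symmetric normalized kernel
        triples (Gaussian / Laplace / uniform): the spatial spectrum never
        exceeds the zero-mode spectrum.
        """
        params = [sp.default_params("SL4", heaviside=True, alpha=a, beta=b)
                  for a, b in ((0.2, 1.0), (1.5, 0.8), (0.3, 2.0))]
        xi = np.concatenate([np.linspace(0.01, 50, 300), [1e2, 1e3]])
        for p in params:
            stable_eqs = [e for e in sp.find_equilibria(p) if e.stable]
            assert stable_eqs
            for _ in range(25):
                kern = random_kernel_triple(rng)
                for eq in stable_eqs:
                    lam0 = np.max(sp.dispersion_sl4(eq.state, p, kern, 0.0).real)
                    worst = max(
                        np.max(sp.dispersion_sl4(eq.state, p, kern, x).real)
                        for x in xi[:: 6]
                    )
                    assert worst <= lam0 + 1e-10


class TestRouthHurwitz:
    def test_triple_root_stable(self):
        assert sp.routh_hurwitz_3(3.0, 3.0, 1.0)  # (lambda+1)^3

    def test_complex_pair_with_positive_real_part(self):
        # lambda^3 + lambda^2 + lambda + 2: roots verified unstable directly
        assert not sp.routh_hurwitz_3(1.0, 1.0, 2.0)
        roots = np.roots([1, 1, 1, 2])
        assert np.max(roots.real) > 0

    def test_reduced_block_stable_for_F_below_r(self):
        """Case (ii): the 3x3 block cannot destabilize when F <= r."""
        p = sp.default_params("RL-SL4", heaviside=True, alpha=2.0, beta=2.0,
                              r=0.84)
        kern = sp.gaussian_kernels(0.05, 0.1, 0.4, sigma_t=0.25)
        for eq in sp.find_equilibria(p):
            if not eq.stable or eq.is_all_grass:
                continue
            assert eq.state.F <= p.r
            for xi in np.linspace(0, 60, 121):
                jt = sp.fourier_transform(kern["JT"], xi)
                M = reduced_block_sl4(eq.state, p, jt)
                a2 = -np.trace(M)
                a1 = (
                    np.linalg.det(M[np.ix_([0, 1], [0, 1])])
                    + np.linalg.det(M[np.ix_([0, 2], [0, 2])])
                    + np.linalg.det(M[np.ix_([1, 2], [1, 2])])
                )
                a0 = -np.linalg.det(M)
                assert sp.routh_hurwitz_3(a2, a1, a0)
                assert np.max(np.linalg.eigvals(M).real) < 0


class TestTuringScans:
    def test_dirac_kernels_never_pattern(self):
        """All transforms identically one collapse the dispersion to lambda_0."""
        p = sp.default_params("RL-GF")
        kern = {"w": sp.make_dirac(), "JF": sp.make_dirac(), "R": sp.make_dirac()}
        tm = sp.turing_scan(p, ("alpha", np.linspace(1, 6, 11)),
                            ("r", np.linspace(0.5, 1.0, 6)), kern)
        assert not tm.turing_space.any()
        finite = np.isfinite(tm.max_growth)
        assert np.all(tm.max_growth[finite] < 0)

    def test_absent_cells_are_nan(self):
        p = sp.default_params("RL-GF")
        kern = sp.gaussian_kernels(0.05, 0.1, 0.4)
        tm = sp.turing_scan(p, ("alpha", np.array([0.3])), ("r", np.array([0.9])),
                            kern)  # all-grass only: no stable interior state
        assert np.isnan(tm.max_growth[0, 0])

    def test_turing_space_inside_necessary_region(self):
        """Pattern cells require N > 0 and exist for the wide resource kernel."""
        pre = sp.load_preset("fig3")
        tm = sp.turing_scan(pre.params, ("alpha", np.linspace(1.0, 6.0, 26)),
                            ("r", np.linspace(0.4, 1.0, 25)), pre.kernels)
        assert tm.turing_space.sum() > 0
        assert np.all(tm.max_N[tm.turing_space] > 0)

    def test_onset_empty_for_dirac(self):
        p = sp.default_params("RL-GF", r=0.84)
        kern = {"w": sp.make_dirac(), "JF": sp.make_dirac(), "R": sp.make_dirac()}
        assert sp.turing_onset(p, kern, (3.0, 6.0), n_scan=31) == []

    def test_restabilization_moves_with_resource_width(self, gf_params):
        """Shrinking sigma_R narrows the instability window."""
        top = sp.gaussian_kernels(0.025, 0.1, 0.15)
        mid = sp.gaussian_kernels(0.025, 0.1, 0.10)
        c_top = sp.turing_onset(gf_params, top, (3.9, 5.5), n_scan=33)
        c_mid = sp.turing_onset(gf_params, mid, (3.9, 5.5), n_scan=33)
        assert max(c_top) > max(c_mid)
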