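"""Tests for post-inference analyses."""

import itertools

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from cgbeads.analysis import (
    anm_modes,
    cross_correlation,
    fit_power_law,
    max_cross_correlation,
    mode_overlap,
    path_length,
    pmf_from_rdf,
    radius_of_gyration,
    rdf,
    render_model_to_map,
    reorder_beads,
    superpose,
    tps_interpolate,
)
from cgbeads.exceptions import ConnectivityError, UndefinedCorrelationError
from cgbeads.potential import lambda_to_lj, pair_energy
from cgbeads.structure_io import DensityMap


def brute_force_open_path(X):
    K = len(X)
    best, best_len = None, np.inf
    for perm in itertools.permutations(range(K)):
        if perm[0] > perm[-1]:
            continue  # skip reversals
        length = path_length(X, np.array(perm))
        if length < best_len:
            best, best_len = perm, length
    return np.array(best), best_len


class TestRadiusOfGyration:
    def test_two_points(self):
        assert radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)

    def test_single_point(self):
        assert radius_of_gyration([[3, 4, 5]]) == 0.0

    def test_uniform_sphere_surface(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((50_000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        R = 7.5
        assert radius_of_gyration(u * R) == pytest.approx(R, rel=0.01)

    def test_weighted(self):
        # weights (1, 3) at 0 and 4: centroid 3, rg = sqrt((9 + 3)/4)
        rg = radius_of_gyration([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])
        assert rg == pytest.approx(np.sqrt(3.0))


class TestRdf:
    def test_two_beads_single_bin(self):
        X = np.array([[0.0, 0, 0], [3.1, 0, 0]])
        res = rdf(X, bin_width=0.25, r_max=5.0)
        nonzero = np.nonzero(res.g)[0]
        assert len(nonzero) == 1
        assert abs(res.bin_centers[nonzero[0]] - 3.1) <= 0.25

    def test_ideal_gas_plateau(self):
        rng = np.random.default_rng(0)
        L, K, F = 40.0, 2000, 30
        frames = rng.uniform(0, L, (F, K, 3))
        res = rdf(frames, bin_width=0.25, r_max=3.0)
        n_pairs = F * K * (K - 1) / 2
        for r, g in zip(res.bin_centers, res.g):
            if r < 0.3 or r > 2.0:
                continue
            expected_counts = n_pairs * 4 * np.pi * r**2 * 0.25 / L**3
            sigma = 1.0 / np.sqrt(expected_counts)
            boundary_corrected = 1.0 - 1.5 * r / L
            assert abs(g - boundary_corrected) < 3 * sigma * boundary_corrected

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 10, (3, 50, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = frames @ Q.T + np.array([100.0, -50.0, 25.0])
        a = rdf(frames, bin_width=0.5, r_max=12.0)
        b = rdf(moved, bin_width=0.5, r_max=12.0)
        np.testing.assert_allclose(a.g, b.g, rtol=1e-8)

    def test_lj_fluid_first_peak_at_twice_rcg(self, lj_fluid):
        frames, spec = lj_fluid
        lj = lambda_to_lj(spec.lambdas)
        res = rdf(frames[::10], bin_width=0.1, r_max=4.0)
        assert abs(res.first_peak - 2 * lj.r_cg) <= 0.1


class TestPmf:
    def test_uniform_g_zero_pmf(self):
        from cgbeads.analysis import RDFResult

        res = RDFResult(np.arange(5) + 0.5, np.ones(5), 1.0, 1)
        np.testing.assert_allclose(pmf_from_rdf(res), 0.0)

    def test_g_equals_e(self):
        from cgbeads.analysis import RDFResult

        res = RDFResult(np.arange(3) + 0.5, np.array([1.0, np.e, 1.0]), 1.0, 1)
        pmf = pmf_from_rdf(res)
        assert pmf[1] == pytest.approx(-1.0)

    def test_zero_g_maps_to_inf(self):
        from cgbeads.analysis import RDFResult

        res = RDFResult(np.arange(2) + 0.5, np.array([0.0, 1.0]), 1.0, 1)
        assert np.isinf(pmf_from_rdf(res)[0])

    def test_pmf_minimum_at_rdf_peak(self, lj_fluid):
        frames, _ = lj_fluid
        res = rdf(frames[::10], bin_width=0.1, r_max=4.0)
        pmf = pmf_from_rdf(res)
        assert res.bin_centers[np.argmin(pmf)] == pytest.approx(res.first_peak)

    def test_pmf_structure_differs_from_bare_potential(self, lj_fluid):
        """The PMF of the interacting fluid shows shell structure (several
        local minima) while the bare pair potential has exactly one."""
        frames, spec = lj_fluid
        res = rdf(frames[::10], bin_width=0.1, r_max=3.5)
        pmf = pmf_from_rdf(res)
        finite = np.isfinite(pmf)
        values = pmf[finite]
        minima = sum(
            1
            for i in range(1, len(values) - 1)
            if values[i] < values[i - 1] and values[i] <= values[i + 1]
        )
        assert minima >= 2
        # bare potential: single minimum
        r = np.linspace(0.8, 3.5, 2000)
        e = pair_energy(r, spec.lambdas)
        pot_minima = sum(
            1
            for i in range(1, len(r) - 1)
            if e[i] < e[i - 1] and e[i] <= e[i + 1]
        )
        assert pot_minima == 1


class TestFitPowerLaw:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        y = 2.0 * x**-0.4
        a, b, resid = fit_power_law(x, y)
        assert a == pytest.approx(2.0, rel=1e-10)
        assert b == pytest.approx(-0.4, rel=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_two_points_exact_interpolation(self):
        a, b, resid = fit_power_law([1.0, 4.0], [3.0, 6.0])
        assert 3.0 * 4.0**b == pytest.approx(6.0, rel=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 100, 30)
        y = 1.7 * x**0.31 * np.exp(0.05 * rng.standard_normal(30))
        a, b, _ = fit_power_law(x, y)
        lx, ly = np.log(x), np.log(y)
        n = len(x)
        slope = (n * (lx * ly).sum() - lx.sum() * ly.sum()) / (
            n * (lx**2).sum() - lx.sum() ** 2
        )
        intercept = (ly.sum() - slope * lx.sum()) / n
        assert b == pytest.approx(slope, rel=1e-10)
        assert a == pytest.approx(np.exp(intercept), rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, -2.0], [1.0, 2.0])


class TestReorderBeads:
    def test_line_points_sorted_order(self):
        X = np.array([[0.0, 0, 0], [5.0, 0, 0], [1.0, 0, 0],
                      [4.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        order = reorder_beads(X)
        assert path_length(X, order) == pytest.approx(5.0)
        xs = X[order, 0]
        assert np.all(np.diff(xs) > 0) or np.all(np.diff(xs) < 0)
        # brute force confirms 5.0 is optimal
        _, best_len = brute_force_open_path(X)
        assert best_len == pytest.approx(5.0)

    def test_two_beads(self):
        X = np.array([[0.0, 0, 0], [1.0, 2.0, 2.0]])
        order = reorder_beads(X)
        assert sorted(order) == [0, 1]
        assert path_length(X, order) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_k8(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, (8, 3))
        order = reorder_beads(X)
        _, best_len = brute_force_open_path(X)
        heuristic_len = path_length(X, order)
        assert heuristic_len >= best_len - 1e-9
        assert heuristic_len == pytest.approx(best_len, rel=1e-9)

    def test_never_worse_than_nearest_neighbor(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 10, (40, 3))
        order = reorder_beads(X)
        # nearest-neighbor-only construction for comparison
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(X))
        start = int(np.argmax(np.linalg.norm(X - X.mean(axis=0), axis=1)))
        nn_order = [start]
        remaining = set(range(40)) - {start}
        while remaining:
            nxt = min(remaining, key=lambda j: dist[nn_order[-1], j])
            nn_order.append(nxt)
            remaining.remove(nxt)
        assert path_length(X, order) <= path_length(X, np.array(nn_order)) + 1e-9


class TestRenderAndCrossCorrelation:
    def _template(self, n=12, voxel=1.0):
        return DensityMap(np.zeros((n, n, n)), [voxel] * 3, np.zeros(3))

    def test_single_bead_peak_at_voxel(self):
        template = self._template()
        rendered = render_model_to_map(np.array([[5.0, 5.0, 5.0]]), template, 1.0)
        assert np.unravel_index(np.argmax(rendered.grid), rendered.grid.shape) == (5, 5, 5)

    def test_two_distant_beads_equal_maxima(self):
        template = self._template()
        rendered = render_model_to_map(
            np.array([[3.0, 3.0, 3.0], [8.0, 8.0, 8.0]]), template, 0.8
        )
        a = rendered.grid[3, 3, 3]
        b = rendered.grid[8, 8, 8]
        assert a == pytest.approx(b, rel=1e-6)
        assert a == pytest.approx(rendered.grid.max(), rel=1e-6)

    def test_integrated_density_is_kernel_mass(self):
        template = DensityMap(np.zeros((30, 30, 30)), [1.0] * 3, np.zeros(3))
        beads = np.array([[15.0, 15, 15], [12.0, 18, 14], [18.0, 12, 16]])
        rendered = render_model_to_map(beads, template, 1.5)
        total = rendered.grid.sum() * 1.0**3
        assert total == pytest.approx(3.0, rel=1e-3)

    def test_cc_self_is_one(self):
        rng = np.random.default_rng(0)
        dmap = DensityMap(rng.random((6, 6, 6)), [1.0] * 3, np.zeros(3))
        assert cross_correlation(dmap, dmap) == pytest.approx(1.0)

    def test_cc_negation_is_minus_one(self):
        rng = np.random.default_rng(1)
        dmap = DensityMap(rng.random((6, 6, 6)), [1.0] * 3, np.zeros(3))
        neg = DensityMap(-dmap.grid, [1.0] * 3, np.zeros(3))
        assert cross_correlation(dmap, neg) == pytest.approx(-1.0)

    def test_cc_shuffled_near_zero(self):
        rng = np.random.default_rng(2)
        grid = rng.random((10, 10, 10))
        shuffled = grid.ravel().copy()
        rng.shuffle(shuffled)
        a = DensityMap(grid, [1.0] * 3, np.zeros(3))
        b = DensityMap(shuffled.reshape(10, 10, 10), [1.0] * 3, np.zeros(3))
        assert abs(cross_correlation(a, b)) < 3.0 / np.sqrt(1000)

    def test_zero_variance_raises(self):
        a = DensityMap(np.ones((3, 3, 3)), [1.0] * 3, np.zeros(3))
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation(a, a)

    def test_max_cc_scans_widths(self):
        rng = np.random.default_rng(3)
        beads = rng.uniform(4, 8, (5, 3))
        template = self._template()
        reference = render_model_to_map(beads, template, 1.2)
        cc, width = max_cross_correlation(beads, reference, [0.6, 1.2, 2.4])
        assert width == 1.2
        assert cc == pytest.approx(1.0, abs=1e-9)


class TestAnmModes:
    def test_diatomic_single_stretch_mode(self):
        modes = anm_modes(np.array([[0.0, 0, 0], [1.5, 0, 0]]), cutoff=2.0)
        assert modes.n_zero_modes == 5
        nonzero = modes.eigenvalues[modes.eigenvalues > 1e-8 * modes.eigenvalues.max()]
        assert len(nonzero) == 1

    def test_connected_network_six_zero_modes(self):
        rng = np.random.default_rng(4)
        sites = rng.uniform(0, 5, (10, 3))
        modes = anm_modes(sites, cutoff=10.0)
        assert modes.n_zero_modes == 6

    def test_modes_orthonormal(self):
        rng = np.random.default_rng(5)
        sites = rng.uniform(0, 5, (8, 3))
        modes = anm_modes(sites, cutoff=10.0)
        gram = modes.modes.T @ modes.modes
        np.testing.assert_allclose(gram, np.eye(24), atol=1e-10)

    def test_hessian_matches_finite_difference(self):
        """ANM Hessian equals the numerical second derivative of the
        harmonic network energy E = 1/2 sum (d_ij - d_ij^0)^2 at the
        reference structure."""
        rng = np.random.default_rng(6)
        sites = rng.uniform(0, 4, (6, 3))
        cutoff = 10.0
        from scipy.spatial.distance import pdist

        d0 = pdist(sites)

        def network_energy(flat):
            d = pdist(flat.reshape(-1, 3))
            return 0.5 * np.sum((d - d0) ** 2)

        n = sites.size
        h = 1e-5
        hess_fd = np.zeros((n, n))
        x0 = sites.ravel()
        for i in range(n):
            for j in range(n):
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[i] += h; xpp[j] += h
                xpm[i] += h; xpm[j] -= h
                xmp[i] -= h; xmp[j] += h
                xmm[i] -= h; xmm[j] -= h
                hess_fd[i, j] = (
                    network_energy(xpp) - network_energy(xpm)
                    - network_energy(xmp) + network_energy(xmm)
                ) / (4 * h * h)
        modes = anm_modes(sites, cutoff)
        analytic = modes.modes @ np.diag(modes.eigenvalues) @ modes.modes.T
        np.testing.assert_allclose(analytic, hess_fd, atol=1e-4)

    def test_disconnected_raises(self):
        sites = np.array([[0.0, 0, 0], [1.0, 0, 0], [50.0, 0, 0], [51.0, 0, 0]])
        with pytest.raises(ConnectivityError):
            anm_modes(sites, cutoff=2.0)


class TestModeOverlap:
    def test_parallel(self):
        v = np.array([1.0, 2.0, -1.0])
        assert mode_overlap(v, 3 * v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert mode_overlap([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_parseval_over_complete_basis(self):
        rng = np.random.default_rng(7)
        sites = rng.uniform(0, 5, (7, 3))
        modes = anm_modes(sites, cutoff=10.0)
        delta = rng.standard_normal(21)
        total = sum(
            mode_overlap(modes.modes[:, i], delta) ** 2 for i in range(21)
        )
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            mode_overlap([0.0, 0.0], [1.0, 0.0])

    def test_animation_frames_span_amplitude(self):
        from cgbeads.analysis import mode_animation_frames

        rng = np.random.default_rng(12)
        sites = rng.uniform(0, 5, (6, 3))
        modes = anm_modes(sites, cutoff=10.0)
        frames = mode_animation_frames(sites, modes.mode(7), amplitude=2.0,
                                       n_frames=16)
        assert frames.shape == (16, 6, 3)
        displacement = np.linalg.norm((frames - sites).reshape(16, -1), axis=1)
        assert displacement.max() == pytest.approx(2.0, rel=0.05)
        np.testing.assert_allclose(frames[0], sites)


class TestSuperpose:
    def test_overlap_invariant_under_rigid_motion_of_mobile(self):
        rng = np.random.default_rng(8)
        open_state = rng.uniform(0, 10, (12, 3))
        closed_state = open_state + 0.5 * rng.standard_normal((12, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = closed_state @ Q.T + np.array([30.0, -10.0, 5.0])
        delta_a = (superpose(closed_state, open_state) - open_state).ravel()
        delta_b = (superpose(moved, open_state) - open_state).ravel()
        np.testing.assert_allclose(delta_a, delta_b, atol=1e-8)
        mode = rng.standard_normal(36)
        assert mode_overlap(mode, delta_a) == pytest.approx(
            mode_overlap(mode, delta_b), abs=1e-9
        )


class TestTpsInterpolate:
    def test_reproduces_control_values(self):
        rng = np.random.default_rng(9)
        control = rng.uniform(0, 10, (15, 3))
        values = rng.standard_normal((15, 3))
        out = tps_interpolate(control, values, control)
        np.testing.assert_allclose(out, values, atol=1e-8)

    def test_affine_field_reproduced_everywhere(self):
        rng = np.random.default_rng(10)
        control = rng.uniform(0, 10, (20, 3))
        A = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        values = control @ A.T + b
        query = rng.uniform(0, 10, (30, 3))
        out = tps_interpolate(control, values, query)
        np.testing.assert_allclose(out, query @ A.T + b, atol=1e-7)

    def test_matches_independent_rbf_solver(self):
        rng = np.random.default_rng(11)
        control = rng.uniform(0, 10, (25, 3))
        values = np.sin(control).sum(axis=1, keepdims=True) * np.ones((1, 3))
        query = rng.uniform(1, 9, (20, 3))
        ours = tps_interpolate(control, values, query)
        reference = RBFInterpolator(control, values, kernel="linear", degree=1)(query)
        np.testing.assert_allclose(ours, reference, atol=1e-6)

    def test_too_few_controls_raise(self):
        with pytest.raises(Exception):
            tps_interpolate(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((1, 3)))
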