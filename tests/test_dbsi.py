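import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
import dbsidnn as dd
from dbsidnn.dbsi import DbsiFitConfig, _inner_nnls, _iso_columns
from dbsidnn.errors import DomainError, ValidationError


class TestSpectrumGrid:
    def test_default_grid_shape(self, grid):
        assert grid.n == 41
        assert grid.d_values[0] == 0.0
        assert grid.d_values[-1] == 4.0
        # trapezoid weights integrate a constant exactly
        assert np.isclose(np.sum(grid.weights), 4.0)

    def test_upper_limit_must_clear_free_band(self):
        with pytest.raises(ValidationError):
            dd.default_grid(0.0, 2.5, 11)

    @pytest.mark.parametrize(
        "d_spike, expected_band",
        [(0.2, 0), (1.0, 1), (0.3, 0), (3.0, 1), (3.2, 2)],
    )
    def test_band_assignment_boundaries_go_low(self, grid, params_factory, d_spike, expected_band):
        # a node exactly on a boundary belongs to the lower band
        params = params_factory(grid, spikes=[(d_spike, 1.0)])
        fractions = dd.spectrum_fractions(params.iso_spectrum, grid)
        assert np.isclose(fractions[expected_band], 1.0)
        assert np.isclose(sum(fractions), 1.0, atol=1e-9)

    def test_band_sum_equals_total(self, grid):
        rng = np.random.default_rng(0)
        spec = rng.uniform(0, 1, grid.n)
        r, h, f = dd.spectrum_fractions(spec, grid)
        assert np.isclose(r + h + f, np.sum(spec * grid.weights), atol=1e-9)


class TestFiberFa:
    def test_stick_limit(self):
        assert dd.fiber_fa(1.7, 0.0) == 1.0

    def test_isotropic_limit(self):
        assert dd.fiber_fa(1.0, 1.0) == 0.0

    def test_matches_general_three_eigenvalue_formula(self):
        # general FA with l2 = l3 as the independent oracle
        def general_fa(l1, l2, l3):
            ev = np.array([l1, l2, l3])
            md = ev.mean()
            return np.sqrt(1.5 * np.sum((ev - md) ** 2) / np.sum(ev**2))

        for lpar, lperp in [(1.7, 0.3), (2.0, 0.5), (1.2, 1.0), (0.9, 0.0)]:
            assert np.isclose(dd.fiber_fa(lpar, lperp), general_fa(lpar, lperp, lperp), atol=1e-12)
        assert np.isclose(dd.fiber_fa(1.7, 0.3), 1.4 / np.sqrt(3.07), atol=1e-9)

    def test_zero_tensor_rejected(self):
        with pytest.raises(DomainError):
            dd.fiber_fa(0.0, 0.0)


class TestForwardModel:
    def test_normalized_params_give_unit_b0(self, scheme, grid, params_factory):
        params = params_factory(
            grid,
            orientations=[[0, 0, 1]],
            lambda_par=[1.7],
            lambda_perp=[0.3],
            fractions=[0.6],
            spikes=[(1.0, 0.4)],
        )
        sig = dd.dbsi_forward(params, scheme)
        assert np.allclose(sig.values[scheme.b0_mask], 1.0, atol=1e-12)

    def test_pure_isotropic_spike_closed_form(self, grid, params_factory):
        # S(b=1000, D=1.0) = exp(-1)
        dirs = np.vstack([np.zeros(3), np.eye(3), -np.eye(3)])
        bvals = np.array([0.0] + [1000.0] * 6)
        scheme = dd.AcquisitionScheme(directions=dirs, bvalues=bvals)
        params = params_factory(grid, spikes=[(1.0, 1.0)])
        sig = dd.dbsi_forward(params, scheme)
        assert np.allclose(sig.values[1:], np.exp(-1.0), atol=1e-12)

    def test_fiber_plus_free_water_term_by_term(self, grid, params_factory):
        # gradient perpendicular to the fiber at b = 1000:
        # S = 0.7 exp(-0.3) + 0.3 exp(-3)
        dirs = np.vstack([np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [-1, 0, 0], [0, -1, 0], [0, 0, -1]])
        bvals = np.array([0.0] + [1000.0] * 6)
        scheme = dd.AcquisitionScheme(directions=dirs, bvalues=bvals)
        params = params_factory(
            grid,
            orientations=[[0, 0, 1]],
            lambda_par=[1.7],
            lambda_perp=[0.3],
            fractions=[0.7],
            spikes=[(3.0, 0.3)],
        )
        sig = dd.dbsi_forward(params, scheme)
        expected_perp = 0.7 * np.exp(-0.3) + 0.3 * np.exp(-3.0)
        assert np.isclose(sig.values[1], expected_perp, atol=1e-12)  # x gradient
        assert np.isclose(sig.values[2], expected_perp, atol=1e-12)  # y gradient
        expected_par = 0.7 * np.exp(-1.7) + 0.3 * np.exp(-3.0)
        assert np.isclose(sig.values[3], expected_par, atol=1e-12)   # z gradient

    def test_unnormalized_total_fraction_at_b0(self, scheme, grid, params_factory):
        params = params_factory(grid, spikes=[(0.5, 0.4), (2.0, 0.3)])
        sig = dd.dbsi_forward(params, scheme)
        assert np.allclose(sig.values[scheme.b0_mask], 0.7, atol=1e-12)


class TestEstimateOrientations:
    def test_single_fiber_within_5_degrees(self, scheme, grid, params_factory):
        truth = np.array([0.0, 0.0, 1.0])
        params = params_factory(
            grid, orientations=[truth], lambda_par=[1.7], lambda_perp=[0.3],
            fractions=[0.7], spikes=[(3.0, 0.3)],
        )
        sig = dd.dbsi_forward(params, scheme)
        found = dd.estimate_orientations(sig, scheme)
        assert len(found) == 1
        angle = np.degrees(np.arccos(min(1.0, abs(found[0] @ truth))))
        assert angle < 5.0

    def test_pure_isotropic_yields_no_fibers(self, scheme, grid, params_factory):
        params = params_factory(grid, spikes=[(0.8, 1.0)])
        sig = dd.dbsi_forward(params, scheme)
        assert dd.estimate_orientations(sig, scheme) == []

    def test_two_orthogonal_fibers_within_10_degrees(self, scheme, grid, params_factory):
        t1, t2 = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
        params = params_factory(
            grid, orientations=[t1, t2], lambda_par=[1.7, 1.7],
            lambda_perp=[0.2, 0.2], fractions=[0.35, 0.35], spikes=[(3.0, 0.3)],
        )
        sig = dd.dbsi_forward(params, scheme)
        found = dd.estimate_orientations(sig, scheme)
        assert len(found) == 2
        angles = sorted(
            min(np.degrees(np.arccos(min(1.0, abs(f @ t)))) for f in found)
            for t in (t1, t2)
        )
        assert max(angles) < 10.0

    def test_empty_candidate_grid_rejected(self, scheme, grid, params_factory):
        params = params_factory(grid, spikes=[(0.8, 1.0)])
        sig = dd.dbsi_forward(params, scheme)
        with pytest.raises(ValidationError):
            dd.estimate_orientations(sig, scheme, candidate_grid=np.zeros((0, 3)))


class TestFitDbsiVoxel:
    def test_pure_restricted_spike(self, scheme, grid, params_factory):
        params = params_factory(grid, spikes=[(0.2, 1.0)])
        sig = dd.dbsi_forward(params, scheme)
        _, m = dd.fit_dbsi_voxel(sig, scheme)
        assert m.restricted_fraction >= 0.99
        assert m.fiber_fraction <= 0.01

    def test_single_fiber_free_water_recovery(self, scheme, grid, params_factory):
        params = params_factory(
            grid, orientations=[[0, 0, 1]], lambda_par=[1.7], lambda_perp=[0.3],
            fractions=[0.8], spikes=[(3.2, 0.2)],
        )
        sig = dd.dbsi_forward(params, scheme)
        _, m = dd.fit_dbsi_voxel(sig, scheme)
        assert abs(m.water_fraction - 0.20) <= 0.02
        assert abs(m.fiber_fraction - 0.80) <= 0.02
        assert abs(m.fiber_ad - 1.7) / 1.7 <= 0.05
        assert abs(m.fiber_rd - 0.3) / 0.3 <= 0.05

    def test_fraction_conservation_and_quality(self, scheme, grid, params_factory):
        rng = np.random.default_rng(5)
        for _ in range(3):
            f_fib = rng.uniform(0.2, 0.7)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            split = rng.dirichlet([1, 1, 1]) * (1 - f_fib)
            params = params_factory(
                grid,
                orientations=[direction],
                lambda_par=[1.6], lambda_perp=[0.4], fractions=[f_fib],
                spikes=[(0.2, split[0]), (1.0, split[1]), (3.2, split[2])],
            )
            sig = dd.dbsi_forward(params, scheme)
            noisy = dd.add_rician_noise(
                dd.VoxelSignal(values=sig.values * 800, b0_mean=800.0), 30.0, rng
            )
            _, m = dd.fit_dbsi_voxel(noisy, scheme)
            total = m.fiber_fraction + m.restricted_fraction + m.hindered_fraction + m.water_fraction
            assert np.isclose(total, 1.0, atol=1e-6)
            assert m.fiber_ad >= m.fiber_rd >= 0
            assert m.quality in ("ok", "max_iter")

    def test_degenerate_voxel_flagged_not_nan(self, scheme):
        sig = dd.VoxelSignal(values=np.zeros(scheme.K), b0_mean=0.0)
        _, m = dd.fit_dbsi_voxel(sig, scheme)
        assert m.quality == "degenerate"
        assert np.isfinite(m.as_array()[:7]).all()

    def test_residual_not_worse_than_dti(self, scheme, grid, params_factory):
        # the spectrum model must explain mixed voxels at least as well as a
        # single tensor does
        params = params_factory(
            grid, orientations=[[0, 0, 1]], lambda_par=[1.7], lambda_perp=[0.3],
            fractions=[0.6], spikes=[(0.2, 0.1), (3.2, 0.3)],
        )
        sig = dd.dbsi_forward(params, scheme)
        y = sig.normalized()
        fitted, _ = dd.fit_dbsi_voxel(sig, scheme)
        resid_dbsi = np.linalg.norm(dd.dbsi_forward(fitted, scheme).values - y)
        dti = dd.fit_dti(sig, scheme)
        ev, evec = dti.eigenvalues, dti.eigenvectors
        b = scheme.bvalues * 1e-3
        quad = np.einsum("kl,lm,km->k", scheme.directions @ evec, np.diag(ev),
                         scheme.directions @ evec)
        resid_dti = np.linalg.norm(dti.s0 * np.exp(-b * quad) - y)
        assert resid_dbsi <= resid_dti + 1e-9


class TestRegularizationAndOracle:
    def test_nnls_matches_exhaustive_grid_search(self):
        # tiny 5-shell scheme, 5-node spectrum, no fibers: exhaustive
        # non-negative grid search (coarse pass + full 0.01-step box around
        # the coarse optimum) as the oracle for the inner solver
        dirs = np.vstack([np.zeros(3), np.eye(3), -np.eye(3),
                          [[0.70710678, 0.70710678, 0], [0, 0.70710678, 0.70710678],
                           [0.70710678, 0, 0.70710678]]])
        bvals = np.array([0.0, 300.0, 300.0, 600.0, 600.0, 900.0,
                          900.0, 1200.0, 1200.0, 1500.0])
        scheme = dd.AcquisitionScheme(directions=dirs, bvalues=bvals)
        d_nodes = np.array([0.3, 0.8, 1.5, 2.4, 3.5])
        grid5 = dd.SpectrumGrid(d_values=d_nodes, weights=np.ones(5))
        truth = np.array([0.3, 0.0, 0.5, 0.0, 0.2])
        y = _iso_columns(scheme, d_nodes) @ truth
        config = DbsiFitConfig(grid=grid5, reg_weight=0.0)
        coef, _ = _inner_nnls(y, scheme, [], np.array([]), np.array([]), config)
        A = _iso_columns(scheme, d_nodes)

        # brute-force oracle: enumerate all 2^5 KKT active sets; the
        # constrained optimum is the best feasible subset solution
        from itertools import combinations

        best, best_r = np.zeros(5), float(np.linalg.norm(y))
        for size in range(1, 6):
            for subset in combinations(range(5), size):
                cols = list(subset)
                sol, *_ = np.linalg.lstsq(A[:, cols], y, rcond=None)
                if np.any(sol < 0):
                    continue
                x = np.zeros(5)
                x[cols] = sol
                r = float(np.linalg.norm(A @ x - y))
                if r < best_r - 1e-15:
                    best_r, best = r, x
        assert np.allclose(coef, best, atol=0.02)

    def test_increasing_tikhonov_never_adds_peaks(self, scheme, grid, params_factory):
        # smoothing property on a fixed two-spike signal
        params = params_factory(grid, spikes=[(0.2, 0.5), (3.2, 0.5)])
        y = dd.dbsi_forward(params, scheme).normalized()

        def n_peaks(reg):
            config = DbsiFitConfig(reg_weight=reg)
            coef, _ = _inner_nnls(y, scheme, [], np.array([]), np.array([]), config)
            active = coef > 1e-6 * max(coef.max(), 1e-30)
            # count runs of consecutive active nodes
            return int(np.sum(np.diff(np.concatenate([[0], active.view(np.int8)])) == 1))

        weights = [0.0, 1e-4, 1e-3, 1e-2, 1e-1]
        peaks = [n_peaks(w) for w in weights]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))


@given(
    lpar=st.floats(min_value=0.6, max_value=2.5),
    ratio=st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_fa_bounds_property(lpar, ratio):
    lperp = lpar * ratio
    fa = dd.fiber_fa(lpar, lperp)
    assert 0.0 <= fa <= 1.0
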