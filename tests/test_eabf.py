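"""eABF machinery: grids, CZAR estimator, gradient integration, stratification."""

import numpy as np
import pytest

from cvpath.constants import KB
from cvpath.dynamics import LangevinConfig, substream
from cvpath.eabf import (
    BiasGrid,
    ExtendedState,
    StratificationPlan,
    Window,
    convergence_report,
    coordinate_cv,
    czar_gradient,
    integrate_gradient,
    linear_cv,
    run_eabf,
    stratified_eabf,
)
from cvpath.potentials import harmonic_well, make_two_basin_potential


def _gaussian_grid(kappa=2.0, coupling=100.0, temperature=300.0, n=500_000,
                   seed=0, edges=None, lam_equals_z=False):
    """Synthetic grid filled from the closed-form biased-free equilibrium:
    z ~ N(0, kT/kappa), lambda | z ~ N(z, kT/k)."""
    kT = KB * temperature
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, np.sqrt(kT / kappa), n)
    lam = z if lam_equals_z else z + rng.normal(0.0, np.sqrt(kT / coupling), n)
    grid = BiasGrid(edges=[edges if edges is not None
                           else np.linspace(-2.5, 2.5, 51)], full_samples=500)
    idx = np.clip(((z - grid.edges[0][0]) * grid._inv_width[0]).astype(int),
                  0, grid.shape[0] - 1)
    np.add.at(grid.z_counts, idx, 1)
    np.add.at(grid.z_sums[:, 0], idx, z)
    np.add.at(grid.lambda_sums[:, 0], idx, lam)
    return grid


class TestBiasGrid:
    def test_requires_increasing_uniform_edges(self):
        with pytest.raises(ValueError):
            BiasGrid(edges=[np.array([0.0, 1.0, 0.5])])
        with pytest.raises(ValueError):
            BiasGrid(edges=[np.array([0.0, 1.0, 3.0])])

    def test_text_roundtrip(self):
        grid = _gaussian_grid(n=10_000)
        back = BiasGrid.from_text(grid.to_text())
        assert np.array_equal(back.z_counts, grid.z_counts)
        assert np.allclose(back.lambda_sums, grid.lambda_sums)
        assert back.full_samples == grid.full_samples

    def test_merge_is_commutative_and_associative(self):
        a = _gaussian_grid(n=5_000, seed=1)
        b = _gaussian_grid(n=5_000, seed=2)
        c = _gaussian_grid(n=5_000, seed=3)
        ab_c = a.merge(b).merge(c)
        c_ba = c.merge(b).merge(a)
        assert np.array_equal(ab_c.z_counts, c_ba.z_counts)
        assert np.allclose(ab_c.lambda_sums, c_ba.lambda_sums)

    def test_bias_zero_in_unvisited_bins(self):
        grid = BiasGrid(edges=[np.linspace(-1, 1, 11)], full_samples=100)
        assert np.all(grid.bias_force(np.array([0.35])) == 0.0)

    def test_bias_ramp_scales_below_full_samples(self):
        grid = BiasGrid(edges=[np.linspace(-1, 1, 11)], full_samples=100)
        idx = grid.bin_index(np.array([0.0]))
        grid.abf_counts[idx] = 50
        grid.force_sums[idx] = np.array([50.0 * 2.0])  # mean force 2
        # ramp 0.5: |bias| = 1 < |mean force| = 2
        assert np.allclose(grid.bias_force(np.array([0.0])), [-1.0])


class TestCzarEstimator:
    def test_stiff_limit_recovers_gaussian_gradient(self):
        # lambda == z exactly: estimate is -kT dln rho/dz = kappa z
        grid = _gaussian_grid(kappa=2.0, lam_equals_z=True, n=2_000_000)
        g = czar_gradient(grid, 300.0, coupling=[100.0])
        c = grid.centers[0]
        ok = np.isfinite(g[:, 0]) & (grid.z_counts > 2000)
        slope = np.polyfit(c[ok], g[ok, 0], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.02)

    def test_exact_bivariate_samples_recover_harmonic_gradient(self):
        grid = _gaussian_grid(kappa=2.0, coupling=100.0, n=2_000_000)
        g = czar_gradient(grid, 300.0, coupling=[100.0])
        c = grid.centers[0]
        ok = np.isfinite(g[:, 0]) & (grid.z_counts > 5000)
        slope, intercept = np.polyfit(c[ok], g[ok, 0], 1)
        assert slope == pytest.approx(2.0, rel=0.05)
        assert abs(intercept) < 0.05

    def test_lambda_shift_moves_estimate_linearly(self):
        grid = _gaussian_grid(n=200_000)
        shifted = grid.copy()
        shift = 0.37
        shifted.lambda_sums = grid.lambda_sums + shift * grid.z_counts[:, None]
        g0 = czar_gradient(grid, 300.0, coupling=[100.0])
        g1 = czar_gradient(shifted, 300.0, coupling=[100.0])
        ok = np.isfinite(g0[:, 0])
        assert np.allclose(g1[ok, 0] - g0[ok, 0], 100.0 * shift, atol=1e-9)

    def test_empty_grid_raises(self):
        grid = BiasGrid(edges=[np.linspace(-1, 1, 11)])
        with pytest.raises(ValueError, match="no samples"):
            czar_gradient(grid, 300.0)

    def test_low_count_bins_flagged_missing(self):
        grid = _gaussian_grid(n=2_000)
        g = czar_gradient(grid, 300.0, coupling=[100.0], min_count=5)
        tails = np.abs(grid.centers[0]) > 2.0
        assert np.all(np.isnan(g[tails, 0]))


class TestIntegrateGradient:
    def test_1d_linear_gradient(self):
        edges = [np.linspace(0, 1, 11)]
        c = 0.5 * (edges[0][1:] + edges[0][:-1])
        g = np.full((10, 1), 3.0)
        fes = integrate_gradient(g, edges)
        expected = 3.0 * (c - c[0])
        assert np.allclose(fes.values, expected, atol=1e-12)

    def test_2d_consistent_field_recovered(self):
        edges = [np.linspace(-1, 1, 21), np.linspace(-1, 1, 21)]
        cx = 0.5 * (edges[0][1:] + edges[0][:-1])
        cy = 0.5 * (edges[1][1:] + edges[1][:-1])
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        g = np.stack([X, 3.0 * Y], axis=-1)  # grad of (x^2 + 3 y^2)/2
        fes = integrate_gradient(g, edges)
        expected = 0.5 * (X**2 + 3 * Y**2)
        expected -= expected.min()
        assert np.nanmax(np.abs(fes.values - expected)) < 1e-8

    def test_2d_curl_noise_bounded_leakage(self):
        edges = [np.linspace(-1, 1, 21), np.linspace(-1, 1, 21)]
        cx = 0.5 * (edges[0][1:] + edges[0][:-1])
        cy = 0.5 * (edges[1][1:] + edges[1][:-1])
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        g = np.stack([X, 3.0 * Y], axis=-1)
        eps = 0.05
        rot = np.stack([-Y, X], axis=-1) * eps  # pure rotational field
        fes = integrate_gradient(g + rot, edges)
        expected = 0.5 * (X**2 + 3 * Y**2)
        expected -= expected.min()
        dev = fes.values - expected
        dev -= np.nanmean(dev)
        assert np.nanmax(np.abs(dev)) < 5 * eps

    def test_disconnected_components_integrated_separately(self):
        edges = [np.linspace(0, 1, 11)]
        g = np.full((10, 1), 2.0)
        g[4:6, 0] = np.nan
        fes = integrate_gradient(g, edges)
        assert np.isnan(fes.values[4])
        assert np.isfinite(fes.values[0]) and np.isfinite(fes.values[-1])


class TestRunEabf:
    def test_determinism(self):
        pot = harmonic_well(2.0, 1)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 1)
        out = []
        for _ in range(2):
            grid = BiasGrid(edges=[np.linspace(-2, 2, 21)], full_samples=200)
            ext = ExtendedState(coupling=[100.0])
            _, z, lam = run_eabf(pot, cfg, cv, grid, ext, 2000, seed=5,
                                 start=[0.0])
            out.append((z, lam, grid.z_counts.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][2], out[1][2])

    def test_flat_potential_uniform_occupancy_and_zero_force(self):
        flat = harmonic_well(1e-9, 1)  # effectively flat on [-1, 1]
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 1)
        grid = BiasGrid(edges=[np.linspace(-1, 1, 11)], full_samples=200)
        ext = ExtendedState(coupling=[100.0])
        run_eabf(flat, cfg, cv, grid, ext, 150_000, seed=2, start=[0.0])
        occ = grid.z_counts / grid.z_counts.sum()
        assert occ.min() > 0.03  # roughly uniform across 10 bins
        mf = grid.force_sums[:, 0] / np.maximum(grid.abf_counts, 1)
        assert np.nanmax(np.abs(mf[grid.abf_counts > 1000])) < 1.5

    def test_czar_slope_from_dynamics(self):
        # 1D harmonic PMF kappa=2 sampled through the extended system
        pot = harmonic_well(2.0, 1)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 1)
        grid = BiasGrid(edges=[np.linspace(-2.5, 2.5, 51)], full_samples=500)
        ext = ExtendedState(coupling=[100.0])
        run_eabf(pot, cfg, cv, grid, ext, 600_000, seed=3, start=[0.0])
        g = czar_gradient(grid, 300.0, coupling=[100.0])
        c = grid.centers[0]
        interior = np.zeros(grid.shape[0], dtype=bool)
        interior[3:-3] = True  # wall-adjacent bins excluded
        ok = np.isfinite(g[:, 0]) & (grid.z_counts > 500) & interior
        slope = np.polyfit(c[ok], g[ok, 0], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.05)


class TestStratification:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StratificationPlan(windows=[Window(-1.0, 0.1), Window(0.0, 1.0)])

    def test_double_well_stratified_matches_single_run(self):
        pot = make_two_basin_potential(3.0, 2.0, 0.0)
        # 1D projection of the double well: bias along x only
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 2)
        edges = [np.linspace(-1.8, 1.8, 25)]
        ext = ExtendedState(coupling=[50.0])

        single = BiasGrid(edges=edges, full_samples=200)
        run_eabf(pot, cfg, cv, single, ext, 500_000, seed=21, start=[-1.0, 0.0])

        plan = StratificationPlan(windows=[
            Window(-1.8, 0.0, start=np.array([-1.0, 0.0]), n_steps=250_000),
            Window(0.0, 1.8, start=np.array([1.0, 0.0]), n_steps=250_000),
        ])
        ext2 = ExtendedState(coupling=[50.0])
        merged = stratified_eabf(pot, cfg, cv, BiasGrid(edges=edges,
                                                        full_samples=200),
                                 ext2, plan, seed=22)

        def barrier(grid):
            g = czar_gradient(grid, 300.0, coupling=[50.0])
            fes = integrate_gradient(g, grid.edges, grid.z_counts)
            v = fes.values
            ok = np.isfinite(v)
            mid = grid.shape[0] // 2
            return np.nanmax(v[mid - 3: mid + 3]) - np.nanmin(v[ok])

        assert barrier(merged) == pytest.approx(barrier(single), abs=0.2)

    def test_merged_counts_include_inherited_once(self):
        inherited = _gaussian_grid(n=10_000, seed=5)
        pot = harmonic_well(2.0, 1)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 1)
        plan = StratificationPlan(windows=[
            Window(-2.5, 0.0, n_steps=2000), Window(0.0, 2.5, n_steps=2000)])
        merged = stratified_eabf(pot, cfg, cv,
                                 BiasGrid(edges=[np.linspace(-2.5, 2.5, 51)],
                                          full_samples=500),
                                 ExtendedState(coupling=[100.0]), plan, seed=6,
                                 inherited=inherited)
        novel = merged.z_counts.sum() - 10_000
        # inherited statistics counted exactly once; window samples taken
        # while the walker sits beyond a wall are excluded from accumulation
        assert 0 < novel <= 4000


class TestConvergenceReport:
    def test_identical_snapshots_zero_change(self):
        g = _gaussian_grid(n=100_000, seed=8)
        report = convergence_report([g, g.copy(), g.copy()], 300.0,
                                    coupling=[100.0])
        assert report[0]["rms_gradient_change"] == pytest.approx(0.0, abs=1e-12)
        assert "force_error_map" in report[-1]

    def test_insufficient_snapshots_raise(self):
        g = _gaussian_grid(n=1_000)
        with pytest.raises(ValueError):
            convergence_report([g], 300.0)

    def test_gradient_change_decays_with_sampling(self):
        # cumulative snapshots of a converging run: late changes < early/5
        pot = harmonic_well(2.0, 1)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        cv = coordinate_cv([0], 1)
        grid = BiasGrid(edges=[np.linspace(-2.0, 2.0, 21)], full_samples=200)
        ext = ExtendedState(coupling=[50.0])
        snaps = []
        rng = substream(17, "snapshots")
        for chunk in range(12):
            run_eabf(pot, cfg, cv, grid, ext, 30_000, rng, start=[0.0])
            snaps.append(grid.copy())
        report = convergence_report(snaps, 300.0, coupling=[50.0])
        changes = [r["rms_gradient_change"] for r in report]
        # cumulative statistics: the k-th increment re-weights the running
        # mean by ~1/(k+1), so the RMS change shrinks roughly like 1/k
        assert changes[-1] < changes[0] / 5

    def test_bootstrap_error_tracks_standard_error_of_mean_force(self):
        # cumulative snapshots of a single bin accumulating Gaussian force
        # samples of std s: the block-bootstrap error of the mean force must
        # track s/sqrt(total samples) and shrink with more blocks
        s, m = 2.0, 1000  # per-sample std, samples per block
        rng = np.random.default_rng(42)
        edges = [np.array([0.0, 1.0])]

        def cumulative_snapshots(n_blocks):
            snaps = []
            grid = BiasGrid(edges=edges, full_samples=10)
            grid.z_counts[0] = 1  # satisfy the non-empty-grid precondition
            for _ in range(n_blocks):
                grid = grid.copy()
                grid.abf_counts[0] += m
                grid.force_sums[0, 0] += rng.normal(0.0, s * np.sqrt(m))
                snaps.append(grid)
            return snaps

        rep3 = convergence_report(cumulative_snapshots(3), 300.0,
                                  coupling=[1.0], n_boot=400, seed=1)
        rep9 = convergence_report(cumulative_snapshots(9), 300.0,
                                  coupling=[1.0], n_boot=400, seed=1)
        err3 = rep3[-1]["force_error_map"][0, 0]
        err9 = rep9[-1]["force_error_map"][0, 0]
        assert err9 < err3  # more sampling, smaller error
        # both within a factor ~3 of the analytic standard error
        assert err3 == pytest.approx(s / np.sqrt(3 * m), rel=2.0)
        assert err9 == pytest.approx(s / np.sqrt(9 * m), rel=2.0)
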