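"""String method: normalization, reparametrization, swarm updates, averaging."""

import numpy as np
import pytest

from cvpath.constants import KB
from cvpath.dynamics import LangevinConfig
from cvpath.eabf import coordinate_cv
from cvpath.potentials import harmonic_well
from cvpath.stringmethod import (
    NormalizationMap,
    PathString,
    SwarmConfig,
    average_string,
    initialize_string,
    normalize_cvs,
    reparametrize,
    string_convergence,
    swarm_iteration,
    uplift_path,
)


class TestNormalization:
    def test_production_style_endpoints(self):
        # converter projection ~ (5, -10) A; two-state order parameter
        # ~ (+1.4, -1.4) A between the end states
        a, b = np.array([5.0, 1.4]), np.array([-10.0, -1.4])
        norm = normalize_cvs(a, b)
        assert np.allclose(norm.scales, [15.0, 2.8])
        assert np.allclose(norm.normalize(a), [1.0, 1.0])
        assert np.allclose(norm.normalize(b), [0.0, 0.0])

    def test_zero_variation_requires_fallback(self):
        a, b = np.array([1.0, 2.0]), np.array([1.0, 5.0])
        with pytest.raises(ValueError, match="zero total variation"):
            normalize_cvs(a, b)
        norm = normalize_cvs(a, b, fallback_scale=1.0)
        assert norm.scales[0] == 1.0

    def test_roundtrip_exact(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        norm = normalize_cvs(a, b, fallback_scale=1.0)
        raw = rng.normal(size=(7, 4))
        assert np.allclose(norm.denormalize(norm.normalize(raw)), raw, atol=1e-12)


class TestInitializeString:
    def test_midpoint_of_three_images(self):
        path = initialize_string([0.0, 0.0], [2.0, 4.0], 3)
        mid_raw = path.raw_images()[1]
        assert np.allclose(mid_raw, [1.0, 2.0])

    def test_equal_spacing_by_construction(self):
        path = initialize_string([0.0, 1.0], [3.0, -1.0], 32)
        arcs = np.diff(path.arc_lengths())
        assert np.allclose(arcs, arcs[0], rtol=1e-12)
        assert path.n_images == 32

    def test_too_few_images(self):
        with pytest.raises(ValueError):
            initialize_string([0.0], [1.0], 2)


class TestReparametrize:
    def test_collinear_images_equalized(self):
        norm = NormalizationMap([0.0], [1.0])
        path = PathString(np.array([[0.0], [0.2], [1.0]]), norm)
        new = reparametrize(path)
        assert np.allclose(new.images[:, 0], [0.0, 0.5, 1.0], atol=1e-12)

    def test_idempotent_on_equally_spaced(self):
        norm = NormalizationMap([0.0, 0.0], [1.0, 1.0])
        t = np.linspace(0, 1, 9)[:, None]
        path = PathString(np.hstack([t, t**0 * 0.3]), norm)
        new = reparametrize(path)
        assert np.allclose(new.images, path.images, atol=1e-12)

    def test_right_angle_polyline_hand_computed(self):
        norm = NormalizationMap([0.0, 0.0], [1.0, 1.0])
        path = PathString(np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1]],
                                   dtype=float), norm)
        # collapse to corner-heavy spacing first
        path.images = np.array([[0, 0], [0.9, 0], [1, 0], [1, 0.1], [1, 1]],
                               dtype=float)
        new = reparametrize(path)
        expected = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1]])
        assert np.allclose(new.images, expected, atol=1e-12)

    def test_duplicate_adjacent_images_merged(self):
        norm = NormalizationMap([0.0], [1.0])
        path = PathString(np.array([[0.0], [0.5], [0.5], [1.0]]), norm)
        new = reparametrize(path)
        assert np.allclose(new.images[:, 0], [0, 1 / 3, 2 / 3, 1], atol=1e-9)

    def test_tangential_displacement_projected_out(self):
        norm = NormalizationMap([0.0, 0.0], [1.0, 1.0])
        t = np.linspace(0, 1, 11)
        base = np.stack([t, np.zeros_like(t)], axis=1)
        path = PathString(base.copy(), norm)
        # purely tangential displacement of interior images
        shifted = base.copy()
        shifted[1:-1, 0] += 0.01 * np.sin(np.pi * t[1:-1])
        path.images = shifted
        new = reparametrize(path)
        assert np.allclose(new.images, base, atol=1e-6)


class TestSwarmIteration:
    @pytest.fixture()
    def setup(self):
        pot = harmonic_well([2.0, 2.0], 2)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005,
                             scheme="overdamped")
        cv = coordinate_cv([0, 1], 2)
        norm = NormalizationMap([-1.0, -1.0], [2.0, 2.0])
        return pot, cfg, cv, norm

    def test_determinism(self, setup):
        pot, cfg, cv, norm = setup
        path = initialize_string([-1.0, -1.0], [1.0, 1.0], 5, norm=norm)
        scfg = SwarmConfig(restraint_k=[50.0, 50.0], equil_steps=50,
                           swarm_size=5, swarm_steps=10)
        a = swarm_iteration(path, pot, cfg, cv, scfg, seed=3)
        b = swarm_iteration(path, pot, cfg, cv, scfg, seed=3)
        assert np.array_equal(a.images, b.images)
        assert a.iteration == path.iteration + 1

    def test_endpoints_locked(self, setup):
        pot, cfg, cv, norm = setup
        path = initialize_string([-1.0, -1.0], [1.0, 1.0], 5, norm=norm)
        new = swarm_iteration(path, pot, cfg, cv,
                              SwarmConfig(restraint_k=[50.0, 50.0],
                                          equil_steps=50, swarm_size=5,
                                          swarm_steps=10), seed=3)
        assert np.array_equal(new.images[0], path.images[0])
        assert np.array_equal(new.images[-1], path.images[-1])

    def test_drift_matches_ornstein_uhlenbeck(self):
        # overdamped harmonic well: E[z(t) - z0] = (z_min - z0)(1 - e^(-kappa t/gamma))
        kappa, gamma, t_steps, dt = 2.0, 1.0, 40, 0.005
        pot = harmonic_well(kappa, 1)
        cfg = LangevinConfig(temperature=300.0, friction=gamma, timestep=dt,
                             scheme="overdamped")
        cv = coordinate_cv([0], 1)
        from cvpath.dynamics import simulate_langevin, substream
        z0 = 1.2
        s = 200
        finals = np.empty(s)
        inits = np.empty(s)
        rng = substream(99, "ou")
        for i in range(s):
            start = np.array([z0])
            traj = simulate_langevin(pot, cfg, start, t_steps, rng)
            inits[i] = z0
            finals[i] = traj[-1, 0]
        drift = (finals - inits).mean()
        tau = kappa * t_steps * dt / gamma
        expected = (0.0 - z0) * (1 - np.exp(-tau))
        stderr = (finals - inits).std(ddof=1) / np.sqrt(s)
        assert abs(drift - expected) < 3 * stderr

    def test_stationary_image_does_not_drift(self, setup):
        pot, cfg, cv, norm = setup
        # string through the minimum; middle image exactly at it
        path = initialize_string([-1.0, 0.0], [1.0, 0.0], 3,
                                 norm=NormalizationMap([-1.0, -1.0], [2.0, 2.0]))
        scfg = SwarmConfig(restraint_k=[200.0, 200.0], equil_steps=300,
                           swarm_size=60, swarm_steps=20)
        new = swarm_iteration(path, pot, cfg, cv, scfg, seed=8)
        # middle image sits at the free-energy minimum: |drift| small
        assert np.linalg.norm(new.images[1] - path.images[1]) < 0.05


class TestConvergenceAndAveraging:
    def test_identical_history_gives_zero_rmsd(self):
        norm = NormalizationMap([0.0], [1.0])
        imgs = np.linspace(0, 1, 5)[:, None]
        path = PathString(imgs.copy(), norm, history=[imgs.copy(), imgs.copy()])
        series = string_convergence(path)
        assert np.allclose(series, 0.0)
        avg = average_string(path, last_n=3)
        assert np.allclose(avg.images, imgs, atol=1e-12)

    def test_known_offset_rmsd_scaling(self):
        norm = NormalizationMap([0.0, 0.0], [1.0, 1.0])
        imgs = np.stack([np.linspace(0, 1, 8), np.zeros(8)], axis=1)
        moved = imgs.copy()
        delta = 0.3
        moved[4, 1] += delta
        path = PathString(moved, norm, history=[imgs])
        series = string_convergence(path)
        # RMSD over M*D entries with a single delta entry
        assert series[1] == pytest.approx(delta / np.sqrt(8 * 2), rel=1e-12)

    def test_average_of_symmetric_pair_is_midline(self):
        norm = NormalizationMap([0.0, 0.0], [1.0, 1.0])
        t = np.linspace(0, 1, 9)
        up = np.stack([t, 0.2 * np.sin(np.pi * t)], axis=1)
        down = np.stack([t, -0.2 * np.sin(np.pi * t)], axis=1)
        path = PathString(down, norm, history=[up])
        avg = average_string(path, last_n=2)
        assert np.allclose(avg.images[:, 1], 0.0, atol=1e-9)

    def test_last_n_longer_than_history_raises(self):
        norm = NormalizationMap([0.0], [1.0])
        path = PathString(np.linspace(0, 1, 4)[:, None], norm)
        with pytest.raises(ValueError):
            average_string(path, last_n=5)


class TestUplift:
    def test_uncorrelated_extra_cv_stays_at_mean(self):
        # extra coordinate y relaxes in its own harmonic well regardless of x
        pot = harmonic_well([2.0, 8.0], 2)
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005,
                             scheme="overdamped")
        low = coordinate_cv([0], 2)
        extra = coordinate_cv([1], 2)
        norm_low = NormalizationMap([-1.0], [2.0])
        low_path = initialize_string([-1.0], [1.0], 7, norm=norm_low)
        norm_full = NormalizationMap([-1.0, -1.0], [2.0, 2.0])
        lifted, warn = uplift_path(low_path, pot, cfg, low, extra, [100.0],
                                   norm_full, sampling_steps=3000, seed=4)
        raw = lifted.raw_images()
        # y fluctuates around 0 with sd sqrt(kT/8)/sqrt(n_eff); means near 0
        assert np.all(np.abs(raw[:, 1]) < 0.15)
        assert lifted.n_cvs == 2

    def test_window3_smoothing_gain(self):
        # alternating +/-eps profile: window-3 moving average leaves amplitude
        # eps/3 on interior points
        from cvpath.stringmethod import PathString
        eps = 0.3
        prof = np.array([eps * (-1) ** i for i in range(9)])
        sm = prof.copy()
        sm[1:-1] = (prof[:-2] + prof[1:-1] + prof[2:]) / 3.0
        assert np.allclose(np.abs(sm[1:-1]), eps / 3)


class TestSerializationAndConvergenceCall:
    def test_string_table_roundtrip(self):
        norm = NormalizationMap([0.0, -1.0], [2.0, 3.0])
        imgs = np.stack([np.linspace(0, 1, 5), np.linspace(1, 0, 5)], axis=1)
        hist = [imgs * 0.9, imgs * 0.95]
        path = PathString(imgs, norm, iteration=2, history=hist)
        back = PathString.from_table(path.to_table())
        assert np.allclose(back.images, path.images, atol=1e-10)
        assert len(back.history) == 2
        assert np.allclose(back.history[0], hist[0], atol=1e-10)
        assert np.allclose(back.norm.offsets, norm.offsets)
        assert np.allclose(back.norm.scales, norm.scales)

    def test_convergence_call_requires_stable_tail(self):
        from cvpath.stringmethod import is_converged
        norm = NormalizationMap([0.0], [1.0])
        imgs = np.linspace(0, 1, 4)[:, None]
        short = PathString(imgs, norm, history=[imgs] * 3)
        assert not is_converged(short, window=10)
        long_flat = PathString(imgs + 0.05, norm,
                               history=[imgs + 0.05] * 12)
        assert is_converged(long_flat, window=10)


class TestUpliftCoupled:
    def test_extra_cv_tracks_conditional_mean(self):
        # U = x^2 + 2 (y - 0.5 x)^2 : E[y | x] = 0.5 x exactly
        from cvpath.potentials import ModelPotential

        def energy(p):
            p = np.asarray(p, dtype=float)
            return p[..., 0] ** 2 + 2.0 * (p[..., 1] - 0.5 * p[..., 0]) ** 2

        def gradient(p):
            p = np.asarray(p, dtype=float)
            g = np.empty_like(p)
            g[..., 0] = 2 * p[..., 0] - 2.0 * (p[..., 1] - 0.5 * p[..., 0])
            g[..., 1] = 4.0 * (p[..., 1] - 0.5 * p[..., 0])
            return g

        pot = ModelPotential(dimension=2, energy_fn=energy,
                             gradient_fn=gradient,
                             domain=(np.array([-3.0, -3.0]),
                                     np.array([3.0, 3.0])))
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.005)
        low = coordinate_cv([0], 2)
        extra = coordinate_cv([1], 2)
        low_path = initialize_string([-1.0], [1.0], 9,
                                     norm=NormalizationMap([-1.0], [2.0]))
        norm_full = NormalizationMap([-1.0, -1.0], [2.0, 2.0])
        lifted, _ = uplift_path(low_path, pot, cfg, low, extra, [200.0],
                                norm_full, sampling_steps=6000, seed=12)
        raw = lifted.raw_images()
        # lifted y-profile follows the conditional mean 0.5 x
        assert np.max(np.abs(raw[:, 1] - 0.5 * raw[:, 0])) < 0.12
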