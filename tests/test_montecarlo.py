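"""Physics checks of the polarized correlation-transfer Monte Carlo engine."""

import numpy as np
import pytest
from scipy import stats

from sparse_sizer import mie, montecarlo as mc
from conftest import make_medium, N_MEDIUM, WAVELENGTH


def isotropic_mie(n: int = 1801) -> mie.MieResult:
    """Synthetic isotropic, polarization-blind phase matrix."""
    theta = np.linspace(0.0, np.pi, n)
    s11 = np.full(n, 1.0 / (4 * np.pi))
    zeros = np.zeros(n)
    return mie.MieResult(
        size_parameter_x=1.0, rel_index_m=1.1, Qsca=1.0, Qext=1.0, anisotropy_g=0.0,
        theta_grid=theta, S11=s11, S12=zeros, S33=s11.copy(), S34=zeros,
    )


def rayleigh_mie(n: int = 1801) -> mie.MieResult:
    susp = mie.SphereSuspension(radius_a=5e-9, n_particle=1.59, n_medium=1.33,
                                wavelength_vacuum=633e-9)
    return mie.scattering_quantities(susp, theta_grid=np.linspace(0, np.pi, n))


class TestLaunch:
    def test_zero_spot_starts_at_origin(self):
        rng = np.random.default_rng(0)
        cfg = mc.SimConfig(beam_radius=0.0)
        for _ in range(5):
            p = mc.launch(cfg, rng)
            assert np.allclose(p.position, 0.0)
            assert np.allclose(p.direction, [0, 0, 1])
            assert np.allclose(p.stokes, [1, 1, 0, 0])
            assert p.weight == 1.0 and p.sum_q_sq == 0.0

    def test_seeded_launches_reproducible(self):
        cfg = mc.SimConfig(beam_radius=0.01)
        a = [mc.launch(cfg, np.random.default_rng(3)).position for _ in range(1)]
        b = [mc.launch(cfg, np.random.default_rng(3)).position for _ in range(1)]
        assert np.array_equal(a, b)

    def test_mean_launch_radius_of_gaussian_spot(self):
        cfg = mc.SimConfig(beam_radius=0.02)
        rng = np.random.default_rng(5)
        radii = [np.hypot(*mc.launch(cfg, rng).position[:2]) for _ in range(100_000)]
        # Gaussian spot with σ = R/√2 has mean radius R√π/2
        expected = cfg.beam_radius * np.sqrt(np.pi) / 2
        assert np.mean(radii) == pytest.approx(expected, rel=0.01)


class TestPropagation:
    def test_no_absorption_keeps_weight(self):
        medium = mc.TransportMedium(mu_s=2.0, mu_a=0.0, mie=isotropic_mie(),
                                    wavenumber=1.0, motion=mc.MotionModel(D=1e-12))
        p = mc.launch(mc.SimConfig(), np.random.default_rng(0))
        mc.propagate_step(p, medium, np.random.default_rng(1))
        assert p.weight == 1.0

    def test_albedo_weighting(self):
        medium = mc.TransportMedium(mu_s=1.0, mu_a=1.0, mie=isotropic_mie(),
                                    wavenumber=1.0, motion=mc.MotionModel(D=1e-12))
        p = mc.launch(mc.SimConfig(), np.random.default_rng(0))
        absorbed = mc.propagate_step(p, medium, np.random.default_rng(1))
        assert p.weight == pytest.approx(0.5)
        assert absorbed == pytest.approx(0.5)

    def test_mean_free_path(self):
        medium = mc.TransportMedium(mu_s=1.5, mu_a=0.5, mie=isotropic_mie(),
                                    wavenumber=1.0, motion=mc.MotionModel(D=1e-12))
        rng = np.random.default_rng(2)
        n = 200_000
        lengths = np.empty(n)
        for i in range(n):
            p = mc.launch(mc.SimConfig(), rng)
            mc.propagate_step(p, medium, rng)
            lengths[i] = p.path_length
        mean, se = lengths.mean(), lengths.std(ddof=1) / np.sqrt(n)
        assert abs(mean - 1.0 / medium.mu_t) < 3 * se


class TestScatter:
    def test_isotropic_cos_theta_uniform(self):
        iso = isotropic_mie()
        rng = np.random.default_rng(7)
        cfg = mc.SimConfig()
        cos_thetas = []
        for _ in range(30_000):
            p = mc.launch(cfg, rng)
            theta, _ = mc.scatter(p, iso, wavenumber=1.0, rng=rng)
            cos_thetas.append(np.cos(theta))
        stat = stats.kstest(cos_thetas, stats.uniform(loc=-1, scale=2).cdf)
        assert stat.pvalue > 0.01

    def test_rayleigh_azimuthal_density(self):
        """Sampled φ histogram matches 1 + (S12/S11)cos2φ for (1,1,0,0) input."""
        ray = rayleigh_mie()
        rng = np.random.default_rng(8)
        cfg = mc.SimConfig()
        thetas, phis = [], []
        for _ in range(60_000):
            p = mc.launch(cfg, rng)
            theta, phi = mc.scatter(p, ray, wavenumber=1.0, rng=rng)
            thetas.append(theta)
            phis.append(phi)
        thetas, phis = np.asarray(thetas), np.asarray(phis)
        sel = np.abs(thetas - np.pi / 2) < 0.3  # where |S12/S11| is large
        ratio = np.interp(np.pi / 2, ray.theta_grid, ray.S12 / ray.S11)
        hist, edges = np.histogram(phis[sel], bins=24, range=(0, 2 * np.pi), density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        # density at θ≈π/2 averaged over the selected band
        band = np.abs(ray.theta_grid - np.pi / 2) < 0.3
        w = (ray.S11 * np.sin(ray.theta_grid))[band]
        r_eff = np.sum((ray.S12 / ray.S11)[band] * w) / np.sum(w)
        expected = (1 + r_eff * np.cos(2 * centers)) / (2 * np.pi)
        assert np.max(np.abs(hist - expected)) < 0.02
        assert ratio < -0.5  # Rayleigh: strong negative S12/S11 near 90°

    def test_forward_scattering_adds_no_momentum_transfer(self):
        iso = isotropic_mie()
        p = mc.launch(mc.SimConfig(), np.random.default_rng(0))
        p.sum_q_sq = 1.25
        k = 2 * np.pi * N_MEDIUM / WAVELENGTH
        # force θ = 0 through the same update rule used by scatter()
        p.sum_q_sq += 2.0 * k**2 * (1.0 - np.cos(0.0))
        assert p.sum_q_sq == 1.25

    def test_scatter_increments_q_squared(self):
        ray = rayleigh_mie()
        rng = np.random.default_rng(9)
        p = mc.launch(mc.SimConfig(), rng)
        k = 1e7
        theta, _ = mc.scatter(p, ray, wavenumber=k, rng=rng)
        assert p.sum_q_sq == pytest.approx((2 * k * np.sin(theta / 2)) ** 2, rel=1e-9)
        assert abs(np.linalg.norm(p.direction) - 1) < 1e-9
        assert abs(np.dot(p.direction, p.reference)) < 1e-9


class TestDetect:
    def _exiting_packet(self, Q=1.0, qsq=0.0):
        return mc.PhotonPacket(
            position=np.array([0.0, 0.0, 0.0]),
            direction=np.array([0.0, 0.0, -1.0]),
            reference=np.array([1.0, 0.0, 0.0]),
            stokes=np.array([1.0, Q, 0.0, 0.0]),
            weight=1.0,
            sum_q_sq=qsq,
        )

    def test_fully_copolarized_deposits_nothing_in_cross(self):
        grid = mc.empty_grid(mc.SimConfig(grid_npix=11, grid_extent=1.0))
        assert mc.detect(self._exiting_packet(Q=1.0), grid)
        assert grid.intensity_co.sum() == pytest.approx(1.0)
        assert grid.intensity_cross.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_q_sum_gives_flat_g1(self):
        cfg = mc.SimConfig(grid_npix=11, grid_extent=1.0)
        grid = mc.empty_grid(cfg)
        msd = mc.MotionModel(D=1e-12).msd(cfg.time_grid) / 6
        mc.detect(self._exiting_packet(Q=0.0, qsq=0.0), grid, msd)
        tot = grid.g1_co.sum(axis=(0, 1)) + grid.g1_cross.sum(axis=(0, 1))
        assert np.allclose(tot, tot[0])

    def test_backscatter_path_matches_dls_closed_form(self):
        """A θ=π single-scattering path decays as exp(−4Dk²τ)."""
        D, k = 2e-12, 1.3e7
        cfg = mc.SimConfig(grid_npix=11, grid_extent=1.0)
        grid = mc.empty_grid(cfg)
        msd = mc.MotionModel(kind="diffusive", D=D).msd(cfg.time_grid) / 6
        qsq = (2 * k) ** 2
        mc.detect(self._exiting_packet(Q=0.0, qsq=qsq), grid, msd)
        g1 = grid.channel_g1("co")
        assert np.allclose(g1, np.exp(-4 * D * k**2 * cfg.time_grid), rtol=1e-12)

    def test_exit_outside_grid_not_binned(self):
        grid = mc.empty_grid(mc.SimConfig(grid_npix=11, grid_extent=1.0))
        p = self._exiting_packet()
        p.position = np.array([5.0, 0.0, 0.0])
        assert not mc.detect(p, grid)
        assert grid.intensity_co.sum() == 0.0


def single_scatter_oracle(medium, cfg, tgrid):
    """Independent single-scattering prediction of the aggregated g1(τ).

    Numerically integrates the once-scattered detected weight over depth z,
    polar angle θ and azimuth φ: density μt e^{−μt z} for the down leg,
    S11(θ) sinθ for the event, e^{−μt z/|cosθ|} escape survival for the up
    leg, restricted to exits landing on the square detection grid; each
    (θ) contributes decay exp(−MSD(τ)/6 · 2k²(1−cosθ)).
    """
    theta = np.linspace(np.pi / 2 + 1e-3, np.pi - 1e-6, 600)
    z = np.linspace(1e-6, 8.0 / medium.mu_t, 500)
    phi = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    s11 = np.interp(theta, medium.mie.theta_grid, medium.mie.S11)
    half = cfg.grid_extent / 2
    msd6 = medium.motion.msd(tgrid) / 6
    k = medium.wavenumber
    g1 = np.zeros_like(tgrid)
    norm = 0.0
    dz = z[1] - z[0]
    for i, th in enumerate(theta):
        r = z * np.tan(np.pi - th)  # exit radius per depth
        xx = r[:, None] * np.cos(phi)[None, :]
        yy = r[:, None] * np.sin(phi)[None, :]
        inside = ((np.abs(xx) < half) & (np.abs(yy) < half)).mean(axis=1)
        w_z = np.sum(medium.mu_t * np.exp(-medium.mu_t * z * (1 + 1 / abs(np.cos(th)))) * inside) * dz
        w = w_z * s11[i] * np.sin(th)
        norm += w
        g1 += w * np.exp(-msd6 * 2 * k**2 * (1 - np.cos(th)))
    return g1 / norm


class TestRunSimulation:
    def test_seeded_bitwise_reproducibility(self, small_particle_medium):
        cfg = mc.SimConfig(n_photons=3000, rng_seed=42)
        g1 = mc.run_simulation(cfg, small_particle_medium)
        g2 = mc.run_simulation(cfg, small_particle_medium)
        assert np.array_equal(g1.intensity_co, g2.intensity_co)
        assert np.array_equal(g1.g1_cross, g2.g1_cross)

    def test_energy_conservation_audit(self, small_particle_grid):
        a = small_particle_grid.audit
        balance = a["launched"] - (
            a["absorbed"] + a["detected"] + a["lost_outside"]
            + a["roulette_net"] + a["path_capped"]
        )
        assert abs(balance) < 1e-6 * a["launched"]

    def test_nonabsorbing_half_space_returns_nearly_all_light(self, small_particle_medium):
        cfg = mc.SimConfig(n_photons=20000, rng_seed=3)  # default path cap
        g = mc.run_simulation(cfg, small_particle_medium)
        a = g.audit
        assert (a["detected"] + a["lost_outside"]) / a["launched"] >= 0.99

    def test_absorption_prunes_detected_weight(self):
        lo = mc.run_simulation(mc.SimConfig(n_photons=8000, rng_seed=5),
                               make_medium(75e-9, mua_fraction=0.0))
        hi = mc.run_simulation(mc.SimConfig(n_photons=8000, rng_seed=5),
                               make_medium(75e-9, mua_fraction=0.7))
        assert hi.audit["detected"] < lo.audit["detected"]

    def test_siegert_range_and_monotonicity(self, small_particle_grid):
        for ch in ("co", "cross"):
            g2c = small_particle_grid.channel_g2(ch)
            assert np.all(g2c <= 1 + 1e-12) and np.all(g2c >= -1e-12)
            assert np.all(np.diff(g2c) <= 1e-12)

    def test_polarization_memory_mean_exit_radius(self, small_particle_grid):
        """Rayleigh-regime co light exits closer to the beam than cross."""
        g = small_particle_grid
        n = g.intensity_co.shape[0]
        xs = (np.arange(n) + 0.5) * g.pixel_pitch - g.extent / 2
        X, Y = np.meshgrid(xs, xs)
        R = np.hypot(X, Y)
        r_co = (R * g.intensity_co).sum() / g.intensity_co.sum()
        r_cx = (R * g.intensity_cross).sum() / g.intensity_cross.sum()
        assert r_co < r_cx

    def test_cross_channel_decorrelates_faster_for_small_particles(self, small_particle_grid):
        g2co = small_particle_grid.channel_g2("co")
        g2cx = small_particle_grid.channel_g2("cross")
        mid = (g2co > 0.1) & (g2co < 0.9)
        assert np.all(g2cx[mid] < g2co[mid])

    def test_single_scattering_limit_matches_oracle(self, small_particle_medium):
        cfg = mc.SimConfig(n_photons=150_000, rng_seed=4, single_scatter_only=True,
                           grid_extent=1.0, grid_npix=15)
        g = mc.run_simulation(cfg, small_particle_medium)
        tot = g.g1_co.sum(axis=(0, 1)) + g.g1_cross.sum(axis=(0, 1))
        tot = tot / tot[0]
        pred = single_scatter_oracle(small_particle_medium, cfg, g.time_grid)
        sel = pred > 0.05
        assert np.max(np.abs(tot[sel] - pred[sel]) / pred[sel]) < 0.05
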