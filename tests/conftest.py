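import numpy as np
import pytest

from sparse_sizer import mie, montecarlo as mc
from sparse_sizer.synthetic import DynamicsSpec, EnvelopeSpec, ImagingGeometry, generate_stack

WAVELENGTH = 633e-9
N_MEDIUM = 1.33
N_REL = 1.1
VISCOSITY = 1e-3
TEMPERATURE = 293.15


def make_medium(radius_m: float, mu_s_prime: float = 1.0, mua_fraction: float = 0.0,
                n_rel: float = N_REL) -> mc.TransportMedium:
    susp = mie.SphereSuspension(
        radius_a=radius_m,
        n_particle=N_MEDIUM * n_rel,
        n_medium=N_MEDIUM,
        wavelength_vacuum=WAVELENGTH,
    )
    res = mie.scattering_quantities(susp)
    return mc.TransportMedium(
        mu_s=mu_s_prime / (1.0 - res.anisotropy_g),
        mu_a=mua_fraction * mu_s_prime,
        mie=res,
        wavenumber=susp.wavenumber_medium,
        motion=mc.MotionModel(
            kind="diffusive", D=mie.stokes_einstein_D(radius_m, VISCOSITY, TEMPERATURE)
        ),
    )


@pytest.fixture(scope="session")
def small_particle_medium() -> mc.TransportMedium:
    """75 nm spheres at μs' = 1/mm — the Rayleigh-regime reference medium."""
    return make_medium(75e-9)


@pytest.fixture(scope="session")
def small_particle_grid(small_particle_medium) -> mc.DetectionGrid:
    cfg = mc.SimConfig(n_photons=30000, rng_seed=11, max_path_lstar=1e4)
    return mc.run_simulation(cfg, small_particle_medium)


@pytest.fixture(scope="session")
def imaging_geometry() -> ImagingGeometry:
    return ImagingGeometry(wavelength=WAVELENGTH, magnification=1.0, f_number=11.0,
                           pixel_pitch=0.006)


@pytest.fixture(scope="session")
def synthetic_pair(imaging_geometry):
    """Co/cross stack pair with analytically known envelopes and dynamics."""
    grain = 2.44 * WAVELENGTH * 2 * 11.0 * 1e3  # mm at the sensor
    env_co = EnvelopeSpec(scale=0.3, c2=-0.2)
    env_cx = EnvelopeSpec(scale=0.3, c4=0.2)
    dyn_co = DynamicsSpec(tau_c=0.005, n_frames=512, frame_rate=1000.0,
                          grain_size=grain, seed=21)
    dyn_cx = DynamicsSpec(tau_c=0.0025, n_frames=512, frame_rate=1000.0,
                          grain_size=grain, seed=22)
    co = generate_stack(env_co, dyn_co, imaging_geometry, (256, 256), channel="co")
    cx = generate_stack(env_cx, dyn_cx, imaging_geometry, (256, 256), channel="cross")
    return {"co": co, "cross": cx, "env_co": env_co, "env_cx": env_cx,
            "dyn_co": dyn_co, "dyn_cx": dyn_cx}
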