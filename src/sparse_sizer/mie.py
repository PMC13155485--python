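"""Mie scattering quantities for monodisperse sphere suspensions.

Everything downstream — phantom-design checks, the polarized Monte Carlo
engine, and the Brownian-dynamics time scales — is parameterized by the
single-sphere Mie solution: the partial-wave coefficients ``(a_n, b_n)``,
the efficiencies ``Qsca``/``Qext``, the anisotropy ``g = <cos θ>``, and the
four independent scattering-matrix rows ``S11, S12, S33, S34``.

Conventions
-----------
* The size parameter is ``x = 2π n_medium a / λ0`` and the relative index
  ``m = n_particle / n_medium``: scattering happens in the medium, and the
  wavenumber used for momentum transfer is ``k = 2π n_medium / λ0``.
* ``S11`` is normalized to integrate to 1 over solid angle,
  ``2π ∫ S11(θ) sinθ dθ = 1``, so it is a probability density for the
  unpolarized scattering angle.
* Scattering-matrix sign conventions follow Bohren & Huffman:
  ``S11 = (|S2|² + |S1|²)/2``, ``S12 = (|S2|² − |S1|²)/2``,
  ``S33 = Re(S2 S1*)``, ``S34 = Im(S2 S1*)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereSuspension",
    "MieResult",
    "OpticalCoefficients",
    "mie_coefficients",
    "amplitude_functions",
    "scattering_quantities",
    "suspension_to_coefficients",
    "stokes_einstein_D",
    "polystyrene_recipe",
    "sweep_table",
    "BOLTZMANN",
]

BOLTZMANN = 1.380649e-23  # J/K

#: handbook densities (kg/m^3) and refractive indices used by the phantom
#: recipes; the suspensions are polystyrene microspheres in aqueous glycerol.
POLYSTYRENE_DENSITY = 1050.0
GLYCEROL_DENSITY = 1261.0
WATER_DENSITY = 1000.0
MIXTURE_PROPERTIES = {
    # glycerol weight fraction -> (density kg/m^3, refractive index)
    0.90: (1235.0, 1.45),
    0.70: (1180.0, 1.44),
    0.60: (1154.0, 1.4130),
}


@dataclass(frozen=True)
class SphereSuspension:
    """A monodisperse sphere suspension illuminated at one vacuum wavelength.

    Lengths are in meters, densities in kg/m^3; ``absorption_mu_a`` is the
    background absorption of the suspending medium in 1/m.
    """

    radius_a: float
    n_particle: float
    n_medium: float
    wavelength_vacuum: float
    weight_fraction: float = 0.0
    particle_density: float = POLYSTYRENE_DENSITY
    medium_density: float = WATER_DENSITY
    absorption_mu_a: float = 0.0

    def __post_init__(self) -> None:
        if not (self.radius_a > 0):
            raise ValueError("radius_a must be positive")
        if self.n_particle < 1 or self.n_medium < 1:
            raise ValueError("refractive indices must be >= 1")
        if not (0 <= self.weight_fraction < 1):
            raise ValueError("weight_fraction must lie in [0, 1)")
        if self.particle_density <= 0 or self.medium_density <= 0:
            raise ValueError("densities must be positive")
        if self.wavelength_vacuum <= 0:
            raise ValueError("wavelength_vacuum must be positive")

    @property
    def size_parameter(self) -> float:
        return 2.0 * np.pi * self.n_medium * self.radius_a / self.wavelength_vacuum

    @property
    def rel_index(self) -> float:
        return self.n_particle / self.n_medium

    @property
    def wavenumber_medium(self) -> float:
        """k = 2π n_medium / λ0, in 1/m."""
        return 2.0 * np.pi * self.n_medium / self.wavelength_vacuum


@dataclass
class MieResult:
    size_parameter_x: float
    rel_index_m: complex
    Qsca: float
    Qext: float
    anisotropy_g: float
    theta_grid: np.ndarray
    S11: np.ndarray
    S12: np.ndarray
    S33: np.ndarray
    S34: np.ndarray

    def __post_init__(self) -> None:
        if self.Qext < self.Qsca - 1e-9 * max(self.Qsca, 1.0):
            raise ValueError("Qext must not be smaller than Qsca")
        if abs(self.anisotropy_g) > 1 + 1e-12:
            raise ValueError("|anisotropy_g| must be <= 1")


@dataclass(frozen=True)
class OpticalCoefficients:
    """Bulk coefficients in 1/mm; ``mfp_lstar`` is the transport mean free
    path 1/μs′ in mm (inf when μs′ = 0)."""

    mu_s: float
    mu_s_prime: float
    mu_a: float
    anisotropy_g: float

    @property
    def mfp_lstar(self) -> float:
        return 1.0 / self.mu_s_prime if self.mu_s_prime > 0 else np.inf


def _n_max(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(x: float, m: complex) -> tuple[np.ndarray, np.ndarray]:
    """Partial-wave Mie coefficients (a_n, b_n) for size parameter ``x`` and
    relative index ``m``.

    Uses the logarithmic derivative by downward recurrence and upward
    Riccati–Bessel recurrences; the series is truncated at
    ``n_max = ceil(x + 4 x^{1/3} + 2)``.
    """
    if not np.isfinite(x) or not np.isfinite(m):
        raise ValueError("x and m must be finite")
    if x <= 0:
        raise ValueError("size parameter x must be positive")

    nmax = _n_max(x)
    mx = m * x

    # logarithmic derivative D_n(mx), downward recurrence with padding
    nstart = nmax + max(15, int(np.ceil(abs(mx))) // 4)
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        rn = n / mx
        D[n - 1] = rn - 1.0 / (D[n] + rn)

    # Riccati-Bessel psi_n(x), chi_n(x), upward
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    prev_psi, prev_chi = psi_m1, chi_m1
    for n in range(1, nmax + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - prev_psi
        chi[n] = (2 * n - 1) / x * chi[n - 1] - prev_chi
        prev_psi, prev_chi = psi[n - 1], chi[n - 1]
    xi = psi - 1j * chi

    n = np.arange(1, nmax + 1)
    Dn = D[1 : nmax + 1]
    fa = Dn / m + n / x
    fb = Dn * m + n / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return a, b


def amplitude_functions(
    a: np.ndarray, b: np.ndarray, cos_theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(θ), S2(θ) from the partial-wave series.

    Evaluates the angular functions π_n, τ_n by their standard upward
    recurrence at each requested angle.
    """
    nmax = len(a)
    mu = np.asarray(cos_theta, dtype=float)
    S1 = np.zeros(mu.shape, dtype=complex)
    S2 = np.zeros(mu.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        S1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        S2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_next = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_next
    return S1, S2


def _default_theta_grid(x: float) -> np.ndarray:
    # 1801 points resolves the phase function up to x ~ 60; for larger
    # spheres the forward lobe (width ~ 1/x) needs a denser grid.
    n = max(1801, int(np.ceil(24.0 * x)) | 1)
    return np.linspace(0.0, np.pi, n)


def scattering_quantities(
    susp: SphereSuspension, theta_grid: np.ndarray | None = None
) -> MieResult:
    """Efficiencies, anisotropy and normalized scattering-matrix rows.

    ``Qsca``, ``Qext`` and ``g`` come from the partial-wave sums; the matrix
    rows are evaluated on ``theta_grid`` (default: uniform, size-adaptive)
    and ``S11`` is normalized to unit integral over solid angle.
    """
    x = susp.size_parameter
    m = susp.rel_index
    a, b = mie_coefficients(x, m)
    n = np.arange(1, len(a) + 1, dtype=float)
    Qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    Qext = (2.0 / x**2) * np.sum((2 * n + 1) * np.real(a + b))

    # asymmetry parameter <cos theta>
    cross = np.sum(
        (n[:-1] * (n[:-1] + 2) / (n[:-1] + 1))
        * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    )
    same = np.sum(((2 * n + 1) / (n * (n + 1))) * np.real(a * np.conj(b)))
    g = (4.0 / (x**2 * Qsca)) * (cross + same) if Qsca > 0 else 0.0

    theta = (
        np.asarray(theta_grid, dtype=float)
        if theta_grid is not None
        else _default_theta_grid(x)
    )
    S1, S2 = amplitude_functions(a, b, np.cos(theta))
    s11 = 0.5 * (np.abs(S2) ** 2 + np.abs(S1) ** 2)
    s12 = 0.5 * (np.abs(S2) ** 2 - np.abs(S1) ** 2)
    s33 = np.real(S2 * np.conj(S1))
    s34 = np.imag(S2 * np.conj(S1))
    norm = 2.0 * np.pi * np.trapezoid(s11 * np.sin(theta), theta)
    if norm > 0:
        s11, s12, s33, s34 = s11 / norm, s12 / norm, s33 / norm, s34 / norm
    return MieResult(
        size_parameter_x=x,
        rel_index_m=m,
        Qsca=float(Qsca),
        Qext=float(Qext),
        anisotropy_g=float(np.clip(g, -1.0, 1.0)),
        theta_grid=theta,
        S11=s11,
        S12=s12,
        S33=s33,
        S34=s34,
    )


def suspension_to_coefficients(
    susp: SphereSuspension, mie: MieResult | None = None
) -> OpticalCoefficients:
    """Bulk μs, μs′, μa (1/mm) of a suspension from its recipe.

    The number density follows from the weight fraction and the mixture
    density: ``ρN = (w ρ_mix / ρ_particle) / (4/3 π a³)``; then
    ``μs = ρN Qsca π a²`` and ``μs′ = μs (1 − g)``.
    """
    if susp.weight_fraction == 0.0:
        return OpticalCoefficients(0.0, 0.0, susp.absorption_mu_a / 1000.0, 0.0)
    res = mie if mie is not None else scattering_quantities(susp)
    w = susp.weight_fraction
    # density of the mixture, assuming additive specific volumes
    rho_mix = 1.0 / (w / susp.particle_density + (1.0 - w) / susp.medium_density)
    a = susp.radius_a
    number_density = (w * rho_mix / susp.particle_density) / (4.0 / 3.0 * np.pi * a**3)
    mu_s = number_density * res.Qsca * np.pi * a**2  # 1/m
    return OpticalCoefficients(
        mu_s=mu_s / 1000.0,
        mu_s_prime=mu_s * (1.0 - res.anisotropy_g) / 1000.0,
        mu_a=susp.absorption_mu_a / 1000.0,
        anisotropy_g=res.anisotropy_g,
    )


def stokes_einstein_D(radius_a: float, viscosity: float, temperature: float) -> float:
    """Brownian diffusion coefficient D = k_B T / (6π η a) in m²/s."""
    if radius_a <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError("radius, viscosity and temperature must be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * radius_a)


def polystyrene_recipe(
    radius_a: float,
    glycerol_weight_fraction: float,
    stock_volume_ml: float,
    diluent_volume_ml: float,
    stock_weight_fraction: float = 0.10,
    wavelength_vacuum: float = 633e-9,
    n_particle: float = 1.59,
) -> SphereSuspension:
    """Polystyrene-in-aqueous-glycerol phantom from its dilution protocol.

    The bead stock is an aqueous suspension at ``stock_weight_fraction``
    (10 wt% as supplied); ``stock_volume_ml`` of it is mixed with
    ``diluent_volume_ml`` of glycerol/water pre-mix.  The final particle
    weight fraction is computed from the volumetric dilution with handbook
    densities, rather than taken from the nominal rounded label, because the
    bulk scattering coefficient is linear in the true particle load.
    """
    try:
        medium_density, n_medium = MIXTURE_PROPERTIES[round(glycerol_weight_fraction, 2)]
    except KeyError:
        raise ValueError(
            f"no handbook data for glycerol weight fraction {glycerol_weight_fraction}"
        ) from None
    rho_stock = 1.0 / (
        stock_weight_fraction / POLYSTYRENE_DENSITY
        + (1.0 - stock_weight_fraction) / WATER_DENSITY
    )
    # diluent density: pure glycerol for the 90% recipe, otherwise the pre-mix
    if glycerol_weight_fraction >= 0.9:
        rho_diluent = GLYCEROL_DENSITY
    else:
        rho_diluent = medium_density
    mass_stock = stock_volume_ml * rho_stock / 1000.0  # grams per ml * ml
    mass_beads = stock_weight_fraction * mass_stock
    mass_total = mass_stock + diluent_volume_ml * rho_diluent / 1000.0
    return SphereSuspension(
        radius_a=radius_a,
        n_particle=n_particle,
        n_medium=n_medium,
        wavelength_vacuum=wavelength_vacuum,
        weight_fraction=mass_beads / mass_total,
        particle_density=POLYSTYRENE_DENSITY,
        medium_density=medium_density,
    )


def sweep_table(
    radii: np.ndarray,
    template: SphereSuspension,
) -> "list[dict[str, float]]":
    """(a, μs, μs′, g) rows for a sweep of radii at a fixed recipe —
    the phantom-design table."""
    rows = []
    for a in np.asarray(radii, dtype=float):
        susp = SphereSuspension(
            radius_a=float(a),
            n_particle=template.n_particle,
            n_medium=template.n_medium,
            wavelength_vacuum=template.wavelength_vacuum,
            weight_fraction=template.weight_fraction,
            particle_density=template.particle_density,
            medium_density=template.medium_density,
            absorption_mu_a=template.absorption_mu_a,
        )
        coeff = suspension_to_coefficients(susp)
        rows.append(
            {
                "radius_a_m": float(a),
                "mu_s_per_mm": coeff.mu_s,
                "mu_s_prime_per_mm": coeff.mu_s_prime,
                "anisotropy_g": coeff.anisotropy_g,
            }
        )
    return rows
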