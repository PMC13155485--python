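# sparse-sizer

Particle sizing in turbid media from the spatiotemporal statistics of
polarized laser speckle.

## The problem

Tissues, biofluids and many soft materials are dense suspensions of
scatterers — organelles, vesicles, cells, fibers — whose sizes span
10 nm to 10 μm. Classical sizing tools (dynamic light scattering, laser
diffraction) require transparent, singly scattering samples and prior
knowledge of concentration and refractive contrast, so they cannot size
particles *inside* an opaque specimen. This package implements an
alternative: illuminate the sample with a focused, linearly polarized
laser beam, image the diffusely backscattered speckle in the co- and
cross-polarized channels, and read the average scatterer radius out of
four spatiotemporal statistics of those speckle movies.

## The method

From the co-/cross-polarized speckle frame series `I∥(x,y,t)`,
`I⊥(x,y,t)` the package computes the peak-normalized intensity envelopes
`Î∥`, `Î⊥`, their 30%-of-peak iso-contours, and the contrast-normalized
intensity autocorrelations `g2∥(t)`, `g2⊥(t)`, and from these four
metrics:

| metric | definition | what it senses |
|---|---|---|
| `X1` | `Î∥(φ=0°)/Î∥(φ=90°)`, radially averaged in the contour annulus | angular anisotropy of the co-envelope (dipole → four-leaved transition) |
| `X2` | `4πA/P²` of the `Î⊥` contour | circularity of the cross-envelope (star-like near `a ≈ λ`) |
| `X3` | `log g2⊥ / log g2∥` at the lag of widest separation | differential decorrelation of the two channels |
| `X4` | `√(A/π)` of the `Î⊥` contour (mm) | spatial extent of the diffuse cross-envelope |

A polarized correlation-transfer Monte Carlo engine (Stokes-vector
photon packets scattered off the Mie phase matrix, with per-path momentum-
transfer accumulation `Σq²` that yields `g1(τ) = ⟨exp(−MSD(τ)/6·Σq²)⟩`)
simulates these metrics over a library of radius `a`, reduced scattering
`μs′ ∈ [0.25, 4] mm⁻¹`, absorption `μa ∈ [0, 0.7 μs′]` and refractive
contrast `n_rel ∈ [1.03, 1.2]`. The library's metric space is partitioned
by k-means (k chosen by silhouette score) and a stepwise regression of
`log a` (linear `a` in the low-turbidity cluster) on `X1..X4` and their
pairwise interactions is fitted per cluster. A new measurement is assigned
to the nearest cluster centroid and its equation returns the radius; a
cross-envelope peak displaced beyond half the contour radius switches to
the low-`n_rel` model set automatically.

## Worked example

Simulate a 75 nm suspension at `μs′ = 1 mm⁻¹` and extract its metrics:

```python
from sparse_sizer import mie, montecarlo as mc
from sparse_sizer.metrics import extract_metrics

susp = mie.SphereSuspension(radius_a=75e-9, n_particle=1.33 * 1.1,
                            n_medium=1.33, wavelength_vacuum=633e-9)
res = mie.scattering_quantities(susp)
medium = mc.TransportMedium(
    mu_s=1.0 / (1 - res.anisotropy_g), mu_a=0.0, mie=res,
    wavenumber=susp.wavenumber_medium,
    motion=mc.MotionModel(kind="diffusive",
                          D=mie.stokes_einstein_D(75e-9, 1e-3, 293.15)))
grid = mc.run_simulation(mc.SimConfig(n_photons=30000, rng_seed=11), medium)
mv = extract_metrics(grid, grid, sim_smooth_px=2.5, polarization_axis_deg=90.0)
print(f"X1={mv.X1:.3f} X2={mv.X2:.3f} X3={mv.X3:.3f} X4={mv.X4:.3f} mm")
```

prints

```
X1=0.572 X2=0.748 X3=1.825 X4=1.047 mm
```

— the Rayleigh-regime signature: a co-envelope dimmed across its bright
axis (`X1 < 1`), a cross channel decorrelating almost twice as fast as the
co channel (`X3 ≈ 1.8`), and a diffuse halo of about one transport mean
free path (`X4 ≈ 1 mm` at `l* = 1 mm`). At this photon count the contour
still carries Monte Carlo noise, which lowers the circularity `X2`
somewhat below its converged value.

The same workflow is scriptable from the shell: `sparse simulate`,
`sparse metrics`, `sparse build-library`, `sparse train`, `sparse predict`,
`sparse map`, `sparse smear`, `sparse synth`, `sparse mie`,
`sparse dilution` (see `sparse --help`).

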