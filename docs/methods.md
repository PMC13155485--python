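# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline. Values quoted as defaults are the package's
fixed study conditions; every empirical number here is computed by the
test suite or `scripts/acceptance.py`, not transcribed from elsewhere.

## Mie optics

Single-sphere scattering uses the standard partial-wave series with the
logarithmic derivative computed by downward recurrence and Riccati–Bessel
functions by upward recurrence, truncated at `n_max = ceil(x + 4x^{1/3} + 2)`.
The scattering matrix rows `S11, S12, S33, S34` follow the Bohren & Huffman
sign conventions; `S11` is normalized to unit integral over solid angle so
it doubles as the sampling density of the transport engine. The θ grid is
uniform with `max(1801, 24·x)` points: 1801 resolves the phase function up
to `x ≈ 60`, and the size-adaptive rule keeps the forward lobe (width
~1/x) of 10 μm spheres (`x ≈ 140`) sampled by several points.

Suspension recipes convert to bulk coefficients through the number density
`ρN = w·ρ_mix/ρ_particle / (4/3 π a³)` with handbook densities
(polystyrene 1.05, glycerol 1.261, 90% w/w aqueous glycerol 1.235 at
n = 1.45, 70% w/w 1.18 at n = 1.44, all g/cm³). For the dilute bead
phantoms the particle weight fraction is derived from the dilution
protocol itself (e.g. 100 μl of 10 wt% aqueous stock into 900 μl glycerol
→ 0.813 wt%) rather than from the rounded nominal "1 wt%", because μs′ is
linear in the true particle load; with that convention the five design
values (0.77, 1.08, 0.81, 3.0, 0.63 mm⁻¹) are reproduced to within a few
percent, against a stated 15% acceptance band dominated by the density
assumptions.

The refractive contrast of the 70% glycerol recipe is taken as the
quotient of the constituent indices, 1.59/1.44 = 1.104.

## Polarized correlation-transfer Monte Carlo

Photon packets carry position, direction, a reference axis that anchors
the Stokes frame, a Stokes vector renormalized to `I = 1`, a weight, and
the accumulated squared momentum transfer `Σq²`. Per event:

* free path `s ~ Exp(μt)`; absorption by albedo weighting
  (`w ← w·μs/μt`), with Russian roulette below `10⁻⁴` (survival 0.1);
* `θ` sampled by inverse CDF of `S11 sinθ`; `φ` by rejection against
  `1 + (S12/S11)(Q cos2φ + U sin2φ)` (bound `1 + |S12/S11|·√(Q²+U²)`);
  because the pair is drawn exactly from the polarized single-scattering
  density, renormalizing the scattered Stokes vector to `I = 1` is the
  exact importance-sampling compensation and no weight factor beyond the
  albedo appears;
* the reference axis rotates by φ about the direction, the direction
  tilts by θ in the (reference, direction) plane, and the sphere Mueller
  matrix applies in that scattering plane; the triad is re-orthonormalized
  each event;
* `Σq² += 2k²(1−cosθ)` with `k = 2πn_medium/λ0`.

At a surface crossing the Stokes vector is rotated about the exit
direction so the reference aligns with the laboratory x axis, and the
deposits are `w(I±Q)/2` into the co/cross pixel grids. For each lag τ of
a fixed 32-point grid (0 then log-spaced 10⁻⁶–10 s) the field-correlation
accumulator receives `deposit·exp(−MSD(τ)/6·Σq²)` — exact for any MSD
model evaluated on the grid, with constant memory. Aggregated over
pixels, `g2(τ) = (g1(τ)/g1(0))²` matches the contrast-normalized
experimental convention.

Orientation convention: first-principles Rayleigh transport makes the
co-polarized envelope brightest perpendicular to the launch polarization
(two 90° perpendicular-polarized scatterings have unit amplitude, while
the in-plane amplitude carries cos²θ). The metric frame therefore labels
that bright polarization-memory axis as φ = 90°, a fixed 90° rotation
from the launch axis recorded in envelope metadata; with this labeling
X1 < 1 in the Rayleigh regime and rises toward 1 for large particles.

A non-absorbing half-space returns all light eventually, but the path-
length distribution has a `s^{-3/2}` tail, so packets are cut at a total
path of `10⁵ l*` by default (≤ 0.5% of launched weight, keeping the
detected-plus-escaped fraction above 99%). Library builds cut at
`300 l*`: paths longer than that exit far outside the detection grid with
overwhelming probability, and the cheaper cap leaves the on-grid
envelopes and correlations essentially unchanged. Energy is audited
exactly: launched = absorbed + detected + escaped + roulette net
+ path-capped, to 10⁻⁶ relative.

The default boundary is index-matched; a mismatched surface
(`n_rel_boundary ≠ 1`) applies scalar Fresnel reflect/transmit decisions
with specular reflection — adequate for the near-normal exits that
dominate detection, and off by default.

Brownian motion with Stokes–Einstein diffusion at η = 1 mPa·s,
T = 293.15 K (a water-like fluid phantom) is the only motion model used
for calibration; power-law and confined MSD models are exposed for
completeness. λ = 633 nm and n_medium = 1.33 throughout the library.

## Metric extraction

Envelopes are temporal means, peak-normalized. Experimental stacks are
pre-smoothed with σ = grain/2 when residual grain contrast exceeds 5%;
simulated grids are smoothed with σ = 1.5 px (2.5 px in trend scans,
3 px in library builds — chosen once for the photon budgets used there)
and have their 3×3 beam-axis block replaced by the neighborhood median,
since the low-order ballistic spike is not part of the diffuse envelope.

Contours come from subpixel marching squares at 30% of peak; among closed
contours the one enclosing the global maximum wins, holes are ignored.
The polyline is low-passed in polar harmonics (≤ 12 by default, ≤ 8 in
library builds): residual speckle grain puts high-frequency wiggles on
the contour that inflate the perimeter, while the physical envelopes
carry only cos2φ/cos4φ structure, so the truncation removes noise bias
in `X2 = 4πA/P²` without touching real lobes (an exact 2:1 ellipse
changes by < 0.1%).

The annular angular profile averages the envelope over pixels between the
contour's inner and outer circles in 2° azimuth bins (uniform pixel
weighting; empty bins interpolated periodically). `X1` reads the profile
at 0° and 90° averaged over ±9° windows and the 180°-opposite bins — the
window reduces estimator variance and biases a cos4φ modulation by < 1%.

`g2` uses the per-pixel lagged product-moment estimator (FFT over time,
up to 16384 bright pixels), averaged over pixels, then normalized by its
first-lag value; the measured contrast β is reported and values below
0.05 are rejected as static. `X3` resamples both curves onto a common
64-point geometric lag grid and evaluates the log-ratio at the lag of
widest vertical separation restricted to where both curves lie in
[0.05, 0.95]; the published description of `t_max` is ambiguous between
this and the maximal-derivative lag, so the derivative variant is
available as an option. Degenerate separation (< 0.01) returns X3 = 1
with a flag.

## Synthetic speckle generator

The generator is the oracle for the extraction pipeline. A complex
circular-Gaussian field is built by Gaussian spatial filtering of white
noise (intensity-autocovariance FWHM = grain size, default the
diffraction value 2.44λ(1+M)f/# ≈ 34 μm) and temporal AR(1) mixing (exact
for exponential `g1`; stretched-exponential targets use Cholesky mixing
of the full frame-correlation matrix). Intensity = |field|² × envelope,
so single-frame intensities are exponential and the measured g2 obeys the
Siegert relation by construction. Envelopes are separable polar shapes
`radial(r)·(c0 + c2cos2φ + c4cos4φ)` with the angular modulation tapered
to zero within ~0.06 mm of the beam axis — physical diffuse lobes vanish
at the center, and an untapered modulation would place the envelope's
supremum at an angular discontinuity at r = 0 that no finite-resolution
measurement attains, biasing the measured peak normalization (and hence
the 30% contour area) relative to the analytic one. Ground-truth
X1/X2/X4 come from dense-grid evaluation of those continuous functions,
X3 from the closed-form g1 models.

What the generator does not emulate: physically coupled co/cross fields,
partially developed speckle, shot/read noise, drift. Passing the
round-trip tolerances (X1, X2 ≤ 3%, X4 ≤ 2%, X3 ≤ 5%, seed-averaged over
five 512-frame 256² stacks) therefore validates the estimator chain, not
camera artifacts.

## Size model

Library grid (full defaults): 24 log-spaced radii 10 nm–10 μm; μs′ ∈
{0.25, 0.5, 1, 2, 4} mm⁻¹ realized by concentration (μs = μs′/(1−g)) at
fixed n_rel; μa/μs′ ∈ {0, 0.2, 0.45, 0.7}; n_rel ∈ {1.03, 1.067, 1.1,
1.2} trained independently. Per-point seeds derive deterministically from
a base seed. The validation suite uses a reduced 3 μs′ × 3 μa × 2 n_rel ×
24-radius library at 8000 photons/point — about 7 minutes on one CPU —
with the detection extent widened to `8 l*` at low turbidity so the 30%
contour closes.

Clustering: per-metric standardization (X4 is in mm, the others
dimensionless), k-means with 10 restarts, k ∈ 2–8 by maximal mean
silhouette, ties to smaller k. On the reduced library silhouette selects
k = 5, matching the published partitioning — reported as a soft
comparison only, since cluster identities are arbitrary. Per cluster, a
bidirectional stepwise OLS (entry/stay p = 0.05/0.10; AIC variant by
config) selects among the four metrics and their six pairwise
interactions, capped at n/10 terms; the response is `log a`
("exponential" equations), except the lowest-median-μs′ cluster which
uses a linear response in `a` — unless that cluster spans more than 1.5
decades of radius, where a linear law is structurally inadequate and the
log form is used instead. Published per-cluster coefficients are not
transcribed; the equations are re-derived from the package's own library.

Prediction: nearest standardized centroid → that cluster's equation; an
axis-aligned bounding box (+10%) flags extrapolation. The n_rel switch
consults only the measured cross-envelope peak-radial-fraction (> 0.5 →
lowest-n_rel model set; otherwise the tag nearest the tissue average
1.1) — no user-supplied n_rel is ever used. Leave-one-out validation
fixes the clusters from the full fit and refits only the held-out
cluster's regression, which at this library size is indistinguishable
from full refits but 50× cheaper.

## Scan mapping and smear morphometry

Maps are assembled purely from stage coordinates (rounding to the pitch
grid with tolerance pitch/4), so serpentine acquisition order is
irrelevant; failed points stay NaN with recorded reasons, and no spatial
smoothing is applied by default so maps audit against per-point CSVs.

Smear morphometry thresholds (Otsu default) with polarity auto-detected
by comparing the image median to the threshold, fills holes, opens with a
~0.3 μm disk, and filters components to 1–80 μm² (swine red-cell scale);
oversize clumps are excluded, never split. Radii are `√(A/π)`; the
summary SD uses the population convention (n), stated in the output.

## Known limitations

* The engine models monodisperse spheres in a homogeneous half-space; no
  layered media, polydispersity within one simulation, or time gating.
* At the extremes of the size range the metrics flatten (X3 ≈ 1.05 for
  a ≥ 2 μm), so size sensitivity degrades there — the leave-one-out
  tolerance is correspondingly looser (0.5 dex) outside 125 nm–5 μm, and
  the X3-vs-size decay is not perfectly monotone at the very top of the
  range (a ~10 μm Mie-resonance-scale uptick of ~0.02 is reproducible in
  this engine).
* Library photon counts (8000/point in the reduced build) leave visible
  seed noise in X1/X2; the stepwise fits absorb part of it, and the
  quoted recovery error already includes it.
* The Fresnel boundary option is scalar (unpolarized reflectance with
  mirror reflection), a simplification acceptable only near normal exit.
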