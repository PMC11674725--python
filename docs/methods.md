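# Methods

This note documents the models behind `bremspect`, the default parameters and
why they were chosen, and what the simulation does and does not claim about
physical scanners.

## Phantom

The digital phantom follows the NEMA IEC body-phantom layout: a torso-shaped
cross-section built from two circular arcs (radius 115 mm, centres at
x = ±35 mm) joined by straight segments — 300 mm wide, 230 mm tall — with a
central cylindrical lung insert (radius 25 mm) and six coplanar fillable
spheres (10, 13, 17, 22, 28, 37 mm diameter) on a 57.2 mm ring at z = 0,
ordered by diameter at 60° spacing. Defaults fill the spheres at 2.37 MBq/mL
and the background at 0.30 MBq/mL of ⁹⁰Y (nominal contrast R = 7.9); at these
concentrations the whole phantom holds ≈3.1 GBq, consistent with a standard
therapy vial. ⁹⁹ᵐTc is added to the background compartment only, so that any
change in measured sphere contrast is attributable to crosstalk and not to
⁹⁹ᵐTc signal inside the spheres. The axial fill length defaults to 180 mm;
the packaged study truncates it to 90 mm (see *Study conditions*).

Rasterization uses 3³ supersampled fractional occupancy per voxel, which keeps
every compartment-integrated activity within ~0.1% of volume × concentration
and voxelized sphere volumes within 2% of 4/3·π·r³ down to 2 mm spacing.
Attenuation maps assign water µ inside the body and 0.30 × water in the lung
insert, from a built-in log-log-interpolated table (anchors 50–400 keV;
µ_water(150 keV) = 0.151 cm⁻¹) evaluated at the window's midpoint energy.

## Spectra and energy windows

Spectra live on a fixed 1 keV grid over 20–400 keV; windows integrate
half-open [low, high) bins. The ⁹⁰Y bremsstrahlung detected-spectrum shape is
a smooth monotonically decreasing exponential, exp(−E/120 keV) — no published
tabulation of the measured shape exists, so this is an explicit approximation.
The ⁹⁹ᵐTc model is the 140.5 keV photopeak plus a low-energy exponential
scatter tail (30% of counts, 30 keV slope) and a small high-energy tail
(0.66%, 18 keV slope; a pile-up / detector-scatter analog) so that the
160–200 keV window receives a small but nonzero ⁹⁹ᵐTc contribution, as the
measured dual-isotope spectrum shows. Detector energy resolution is Gaussian
with FWHM(E) = 9.9% · 140 keV · √(E/140); broadening is applied per source bin
and the spectrum renormalized.

Each isotope carries a `detected_yield` — the relative number of detectable
photons per decay (⁹⁹ᵐTc 0.89, ⁹⁰Y 0.02). This single number encodes why
dual-isotope imaging is hard: per MBq, ⁹⁹ᵐTc delivers ~35× more counts into
the 90–120 keV window than ⁹⁰Y itself, so 5% contamination multiplies the
window's background severalfold, while the 160–200 keV window sees only a few
percent extra counts and 200–250 keV almost none.

Half-lives are the standard constants (⁹⁹ᵐTc 6.007 h, ⁹⁰Y 64.05 h); decay is
A·2^(−Δt/T½). The same-day scenario (180 MBq ⁹⁹ᵐTc injected, 3 h
planning-to-imaging interval, 2.7 GBq ⁹⁰Y) yields 127.33 MBq ≈ 5%
contamination, matching the highest clinically expected level.

## Acquisition model

The projector is 2.5-D parallel-beam over 64 views / 360° (64 rather than 60
so the 8 OSEM subsets divide the views evenly), circular orbit of radius
250 mm, detector bins equal to the grid columns. Per view it applies, in
order: slice-wise in-plane rotation (bilinear interpolation assembled as a
sparse matrix), voxel-wise attenuation factors exp(−∫µ) accumulated from the
rotated µ map, a distance-dependent Gaussian collimator-detector response
(separable transverse/axial kernels per depth row, σ(d) = σ₀ + slope·d), and
summation along the ray. Septal penetration is an additive component: the
attenuated activity blurred by a wide (σ = 50 mm) Gaussian plus a 20% flat
floor, mixed in with a collimator- and window-dependent weight

|            | 90–120 | 160–200 | 200–250 | σ₀ (mm) | slope (mm/cm) | sensitivity |
|------------|-------:|--------:|--------:|--------:|--------------:|------------:|
| HE         |  0.05  |  0.08   |  0.18   |  2.0    |  0.42         | 1600 c/MBq·s |
| ME         |  0.18  |  0.25   |  0.40   |  1.8    |  0.40         | 2240 c/MBq·s |

The weights grow with window energy (septal penetration worsens for the
harder part of the bremsstrahlung spectrum) and are several times larger for
ME than HE (thinner septa) — this asymmetry, not resolution, is what makes
the HE collimator win on contrast recovery. The geometric blur corresponds to
~13 mm FWHM at 10 cm, a realistic high-energy-collimator figure. Sensitivities
give ≈1.6×10⁷ counts for the reference 20-min 3.2 GBq acquisition in
90–120 keV (detection efficiency ~2×10⁻⁴ of decays); they were set so that
repetition noise on the CRC (SD ≈ 0.005 over 3 repetitions at the default
grid) is several times smaller than the systematic CRC separations between
adjacent contamination levels that the study is designed to resolve.

Expected counts scale as `yield × window-fraction × sensitivity × view-time ×
activity`; counts are independent Poisson draws per bin from a
`numpy.random.default_rng(seed)` stream, with repetitions using seed, seed+1,
… Effective activities are treated as constant over a scan; decay between
repetitions is not modelled (repetitions are i.i.d. noise realizations).

The back-projector applies the exact transposes of every step, so the adjoint
identity ⟨Px, y⟩ = ⟨x, Pᵀy⟩ holds to float precision — the property the EM
convergence guarantees rest on.

## Reconstruction

`local_site` mode is OSEM with the clinical parameters — 10 iterations,
8 subsets (round-robin view assignment, fixed order), attenuation correction
only, uniform scale-correct initialization, followed by a 5 mm FWHM Gaussian
post-filter (periodic boundaries, so the voxel sum is conserved exactly;
σ = FWHM/2.3548). No resolution modelling — the commercial-protocol analog.

`advanced` mode is the model-compensating reconstruction: the OSEM projector
additionally contains the full collimator-detector response (geometric and
broad septal kernels), and the forward step carries two additive terms — the
flat septal floor evaluated on the current image estimate (refreshed each
iteration) and, when a ⁹⁹ᵐTc activity estimate is available (in the study, the
oracle crosstalk sinogram computed from the known ⁹⁹ᵐTc map), the crosstalk
expectation for the target window. Splitting the flat floor out of the system
matrix keeps the multiplicative update well-behaved while the total forward
model remains exactly the simulator's. Advanced mode applies no post-filter by
default. With every correction flag off, `advanced_recon` reduces bit-for-bit
to plain OSEM with a bare projector. Zero-sensitivity voxels are masked out of
the updates; an all-zero sinogram is rejected as degenerate.

On noiseless data with matched models this reconstruction recovers the
background concentration to a fraction of a percent and, given enough
iterations, the sphere contrasts. EM resolution recovery is, however,
asymptotically slow under heavy blur: with the full HE response (σ ≈ 6–19 mm
across the field of view) the 37 mm sphere CRC climbs only from 0.85 to 0.88
between 800 and 25 600 effective subiterations. The packaged parameter-recovery
check therefore runs with a matched moderate-resolution system (distance slope
0.15 mm/cm, everything else identical), where 100 iterations × 16 subsets
reach 97% of the true-map CRC in ~15 s — the check validates that the
algorithm inverts its own forward model, not the convergence speed of EM under
a particular collimator.

## VOIs and CRC

VOIs are placed analytically from the known phantom geometry — the digital
phantom needs no image registration. Sphere VOIs are fractional-occupancy
masks (volumes within 2% of analytic). The sphere mean is a
boundary-corrected, occupancy-weighted estimator,
C_S = (Σ w·v − C_B Σ w(1−w)) / Σ w², which exactly inverts the
sphere/background mixing of boundary voxels: on the true voxelized map the
CRC is 1 for every sphere at any grid spacing, so deviations from 1 in a
reconstruction measure the imaging chain, not the voxelization. (A plain
binary-mask mean dilutes small spheres by ~6h/d at voxel size h and would make
CRC of the truth itself fall well below 1.) The background VOI is the annulus
(39/76 mm radii) around the lung insert, restricted to slices that contain no
sphere voxels and extended axially to a total length of 50 mm; its weights are
a binary ring/axial-band selection times fractional body occupancy, and its
mean uses the same occupancy correction, so partial voxels at the body edge
(mixing with air) are handled while partial voxels at the ring boundary (fully
background) are not over-corrected.

CRC is computed per repetition and aggregated as mean and sample SD (n−1); a
single repetition reports SD 0 with a flag. CRC is invariant under global
rescaling of the volume, so no absolute calibration is needed. Reporting
defaults to the four largest spheres — partial-volume effect and noise
dominate 10 and 13 mm.

## Study conditions and trend checks

The default study (`StudyConfig()`) runs the built-in six-experiment schedule
— scan times 20/20/20/20/25/25 min, collimators HE/ME/ME/HE/HE/ME, ⁹⁰Y
3.2/3.1/3.1/3.0/3.1/3.1 GBq, ⁹⁹ᵐTc 0/0/450/376/189/165 MBq (0/0/15/13/6/5%),
3 repetitions each — in all three windows and both reconstruction modes, on a
64×64 grid at 4.8 mm in-plane, 16 slices at 6 mm, with the phantom's axial
fill truncated to 90 mm so the annulus VOI and spheres are fully contained.
These sizes keep the full study under ~2 min on one CPU. A run is fully
determined by its configuration and seed: identical runs produce byte-identical
CRC tables.

Six trend checks encode the study's qualitative findings; their thresholds are
package-level gates motivated by — not equal to — physical-scanner numbers,
since a kernel-based simulator does not reproduce absolute CRC magnitudes:

- **T-a** 90–120 keV/HE CRC drops to < 0.5× from 0% to ~5% Tc (observed ≈ 0.2×).
- **T-b** 160–200 keV/HE CRC changes < 15% relative over the same step (≈ 6%).
- **T-c** HE ≥ ME at matched window/mode/contamination.
- **T-d** 200–250 keV < 160–200 keV for ⁹⁰Y-only (higher septal weight, fewer
  counts).
- **T-e** compensating reconstruction beats plain OSEM everywhere.
- **T-f** 160–200 keV CRC decreases monotonically over 0 → ~5 → ~14% Tc, for
  both collimator series.

A check whose required combinations were not run reports *not evaluable*
rather than passing silently; disabling the ⁹⁹ᵐTc in the simulator (the
`tc_enabled=False` negative control) makes T-a fail by construction.

## What the simulator does not emulate

- No photon transport: object scatter is folded into the broad septal kernel
  and flat floor; there is no energy-dependent scatter estimate per object.
- Absolute CRC values are not those of any physical scanner; only orderings
  and relative changes are meaningful.
- No detector intrinsic resolution separate from the collimator term, no
  dead-time/pile-up at the count-rate level, no decay within or between
  repetitions, no CT simulation (attenuation maps are analytic), and no
  background-compensation reconstruction.
- The repetition model is pure Poisson noise; physical repetitions also carry
  setup variability, so simulated SDs underestimate experimental ones.

Passing tests therefore demonstrate internal consistency (adjoint exactness,
EM monotonicity, conservation, recovery under matched models, seeded
determinism) and the mechanism-level reproduction of the study's qualitative
findings — not quantitative agreement with scanner measurements.
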