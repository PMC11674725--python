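# bremspect

In-silico image-quality study of **⁹⁰Y bremsstrahlung SPECT in the presence of
⁹⁹ᵐTc** — the dual-isotope situation created by same-day radioembolization,
where the ⁹⁹ᵐTc-MAA planning injection is still in the patient when the
post-treatment ⁹⁰Y scan is acquired.

⁹⁰Y is a pure beta emitter: it is imaged through its continuous bremsstrahlung
X-ray spectrum, which has no photopeak and a very low photon yield per decay.
Even a few percent of ⁹⁹ᵐTc (a 140.5 keV gamma emitter with ~0.89
photons/decay) can therefore flood a low-energy acquisition window and destroy
the contrast of the ⁹⁰Y image. `bremspect` is a simulation library for
quantifying that degradation and for evaluating counter-measures — energy-window
choice (90–120 / 160–200 / 200–250 keV), collimation (high-energy vs
medium-energy parallel-hole) and model-compensating reconstruction — on a
digital NEMA IEC body phantom. It is aimed at nuclear-medicine physicists and
image-reconstruction researchers who want a controlled, fully seeded sandbox
for dual-isotope protocol design.

## What it computes

Image quality is measured as the **contrast recovery coefficient** of each
phantom sphere,

```
CRC = (C_S / C_B − 1) / (R − 1)
```

where `C_S` is the mean reconstructed signal in a sphere VOI, `C_B` the mean in
a background annulus (inner/outer radius 39/76 mm around the lung insert), and
`R = 2.37/0.30 = 7.9` the nominal sphere-to-background activity-concentration
ratio. CRC = 1 is perfect recovery; 0 means the sphere has vanished into the
background.

The pipeline is:

1. **`phantom`** — analytic NEMA IQ phantom (six coplanar spheres 10–37 mm,
   torso body, cylindrical lung insert) rasterized to per-isotope activity maps
   (MBq/mL) and per-window attenuation maps (1/cm) with supersampled fractional
   occupancy.
2. **`spectra`** — detected-energy spectra for ⁹⁰Y bremsstrahlung and ⁹⁹ᵐTc on
   a 1 keV grid, Gaussian energy response (FWHM ∝ √E, 9.9% at 140 keV), window
   count fractions, dual-spectrum composition/subtraction, decay arithmetic.
3. **`acquisition`** — seeded synthetic scanner: rotation-based parallel-beam
   projector with attenuation, distance-dependent collimator blur, a broad
   septal-penetration component, per-window sensitivities and Poisson noise,
   driven by a built-in six-experiment schedule (0–15% ⁹⁹ᵐTc added to the
   background only).
4. **`reconstruction`** — OSEM (10 iterations, 8 subsets, 5 mm Gaussian
   post-filter; the clinical protocol analog) and a model-compensating OSEM
   that puts attenuation and the full collimator-detector response inside the
   projector and adds septal-floor and ⁹⁹ᵐTc-crosstalk terms to the forward
   step. The back-projector is the exact adjoint of the forward projector.
5. **`iq` / `study`** — analytic VOI placement, per-repetition CRC, mean ± SD
   aggregation, CRC-vs-contamination curves, and six qualitative trend checks
   (window collapse at 5% Tc, robustness of 160–200 keV, HE ≥ ME, …).

## Worked example

`python examples/03_simulate_and_reconstruct.py` simulates the ~6%
contamination experiment (3.1 GBq ⁹⁰Y + 189 MBq ⁹⁹ᵐTc, high-energy collimator,
25 min) and reconstructs the 160–200 keV window both ways:

```
experiment 5: 3.1 GBq 90Y + 189.0 MBq 99mTc (6%), HE
simulated counts in 160-200 keV: 4,687,311

sphere  CRC(OSEM)  CRC(compensated)
  17 mm     0.109       0.165
  22 mm     0.137       0.234
  28 mm     0.192       0.454
  37 mm     0.314       0.746
```

Reading: with plain OSEM the 37 mm sphere recovers ~31% of its true contrast;
modelling the collimator response and the crosstalk inside the reconstruction
roughly doubles that. `examples/04_contamination_study.py` sweeps the
contamination levels and shows the standard 90–120 keV window collapsing
(CRC 0.35 → 0.07 at 6% Tc) while 160–200 keV declines only incrementally
(0.34 → 0.32 → 0.29 at 0/6/13%) — the rationale for the robust dual-isotope
protocol. The other examples cover phantom construction and the
spectrum/window arithmetic.

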