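# Methods

This note documents the models implemented in `aostain`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Image model and preprocessing

The camera model assumes an 8-bit RGB sensor with linear response
(gamma exponent 1 — enforced; ratios of counts are only ratios of
intensities under linearity), a fixed per-channel dark offset
(default 12 counts, measured with the dust cover on), fixed colour-balance
multipliers (red 550, blue 800 — recorded for provenance, never undone:
the analysis operates on images as saved), and a Bayer colour-filter
mosaic whose firmware fills missing colours by nearest-neighbour copying
within each 2×2 tile.

Preprocessing order is fixed as **downsample, then dark-subtract**:

- *Downsampling* is a 2×2 block mean. The tile holds a single true
  chromatic sample per colour, so averaging collapses the firmware's
  duplicates back to the sensor's real chromatic resolution while
  preserving mean intensity; decimation would arbitrarily privilege one
  sub-pixel. For images whose 2×2 groups are exact duplicates the two
  operations commute with dark subtraction; the order is fixed purely for
  reproducibility.
- *Dark subtraction* clips at zero: counts are non-negative by
  construction, and the handful of pixels driven below the offset by read
  noise carry no usable signal. A provenance guard makes double
  subtraction an error rather than a silent bias of 2×dark.

## Masking and ratio statistics

The cell-wall mask is a simple lower threshold on the dark-subtracted
green channel. The threshold is a required analyst input per image set —
it separates wall signal from lumina and other structures, and depends on
staining and exposure — with an Otsu helper available as a suggestion but
never applied implicitly. Masked pixels where green is exactly zero are
excluded from the ratio (not mapped to infinity) and counted.

Set-level statistics treat the **image as the replication unit**: pixels
within an image are spatially correlated (shared illumination, focus and
section), so the per-image mean ratios are the observations and the 95%
confidence interval is `t(0.975, n−1)·s/√n` over the n images. Pooled
pixel histograms (fixed 0.01-wide bins on [0, 5], overflow accumulated in
the last bin) and pooled channel modes are attached for inspection.
Channel modes use integer bins of width one count with ties broken to the
lowest bin, computed over masked pixels; whether whole-image modes would
differ materially is an open sensitivity question, and masked modes were
chosen because the mask defines the tissue of interest.

## Dimerization equilibrium

For 2M ⇌ D with association constant K and total dye c (monomer
equivalents), mass balance m + 2Km² = c gives the closed-form positive
root, evaluated in the cancellation-free form m = 2c/(1 + √(1 + 8Kc)).
`fraction_dimer` is the fraction of dye *molecules* in dimers, 2d/c — the
quantity relevant to emission partitioning — not the mole fraction of the
dimer species. At K = 5000 L/mol this gives 73% at 1000 μmol/L and 0.98%
at 1 μmol/L.

The spectral mixing model is linear: expected channel counts are a 3×2
matrix (channels × species) times the monomer/dimer emitter densities,
with matrix entries formed by summing emission spectra against camera
quantum-efficiency curves on a 1 nm grid. The default spectra are
synthetic Gaussians (monomer peak 530 nm, dimer peak 640 nm, widths
30 nm) with Gaussian QE stand-ins — **not calibrated**; they reproduce
the qualitative structure (green channel dominated by monomer emission,
red by dimer, with enough spectral overlap to compress the usable ratio
range to roughly 0.5–2.5) and are intended for simulation and testing,
not radiometry.

## ITC dilution-heat correction

Injecting concentrated (substantially dimerized) dye into a dilute cell
dissociates dimers and produces a heat signal that must be removed before
interpreting binding. The model solves the equilibrium (fixed
K = 3040 L/mol, ΔH = −44.4 kJ per mol of dimer formed) in the syringe and
in the cell after every injection and charges each injection

q = ΔH · (n_dimer,after − n_dimer,delivered − n_dimer,before).

Bookkeeping conventions, stated explicitly because they matter at the
1e−12 level the tests demand:

- *Perfusion displacement*: the cell is overfilled and of constant volume
  V (default 1.4 mL, typical of the instrument class; configurable); an
  injection of volume v expels an equal volume of pre-injection mixture
  before equilibration, so c_after = (c_before(V−v) + c_syringe·v)/V.
- *Syringe state*: equilibrated at the syringe concentration by default
  (800 μmol/L is ~66% dimerized at K = 3040); a nominal all-monomer
  convention is selectable.
- Sign: positive = endothermic. With exothermic formation, every
  dilution heat is positive and magnitudes shrink monotonically as the
  cell concentration approaches the syringe's.

Only the dilution term is modelled. The strong AO–carboxylate association
visible in the first injections is *not* fitted (no n/K/ΔH isotherm); the
corrected heats are reported and the strong-site accounting is plain
arithmetic (adsorbed dye / acid groups, in percent).

## Conductometric titration

The analyzer fits three line segments (strong-acid decline, weak-acid
plateau, excess-base rise) with segment boundaries restricted to
inter-point positions, at least 4 points per segment, chosen by exhaustive
search minimizing the total squared residual (prefix-sum closed-form OLS
makes the search O(n²) with O(1) per candidate). Breakpoints V₁ and V₂
are intersections of neighbouring fitted lines; when the middle segment is
collinear with a neighbour (no resolvable plateau) the breakpoints
collapse and the weak-acid content is zero. Only the weak-acid segment is
reported as "acid group content", the carboxyl quantity the method is used
for on pulps. The estimator is invariant to constant conductivity offsets
and scales inversely with sample mass. No CO₂ or dilution corrections are
applied.

## Decay kinetics

Half-life comes from ordinary least squares on ln(absorbance) vs time;
absorbance is assumed proportional to initiator concentration
(Beer–Lambert linear range), so the proportionality constant drops out.
The radical yield n·c₀·V·(1 − 2^(−t/t½)) defaults to two radicals per
decomposition (azo initiator stoichiometry). For a slowly decomposing
initiator (t½ = 436 h) observed over 18 h, the yield is necessarily a
small fraction (~2.8%) of the exhaustion limit; published radical-amount
figures for such conditions are not always reproducible from the
first-order formula, and this module deliberately implements the formula
rather than any particular printed total.

## Synthetic data: what it does and does not emulate

The micrograph generator emulates the *measurement chain*, not wood
anatomy: a periodic honeycomb of lumina, secondary-wall rings and
middle-lamella borders defined on the half-resolution (true chromatic)
grid; per-region monomer/dimer densities pushed through the mixing model;
one Poisson (shot-noise) sample per colour per 2×2 group, nearest-
neighbour copied across the group (the firmware's Bayer interpolation);
the fixed dark offset added after the shot noise (it is an electronic
bias, not a photon signal); quantization to 8 bits with clipping.
Region densities are obtained by *inverting* the mixing model so planted
region ratios are exact at the expected-signal level (defaults: walls at
R/G = 0.97, middle lamellae at 1.8, lumina nearly dark). An oxidation
knob (`green_loss`) scales only the monomer densities, reproducing the
empirical signature that mild oxidation suppresses green emission and
raises the ratio while moving the red channel much less.

Replicate image sets apply independent multiplicative jitter (default
relative SD 0.02) to the monomer and dimer densities per image, emulating
location-to-location variation between imaged fields; this is what makes
images a meaningful replication unit for the t-interval. Not emulated:
optics (PSF, out-of-focus haze), anatomical detail (pits, rays, earlywood/
latewood), bleaching, stain-concentration history, or spectral changes of
the dye with binding site. Passing round-trip tests therefore demonstrate
correctness of the computational chain under the stated camera and noise
model, not robustness to real-specimen variability.

The titration generator emulates the described instrument: 20 μL pump
pulses with one conductivity reading each, runs of ~18 mL total (about 90
minutes at 10 pulses/min, well past equivalence), sample mass defaulted to
put 50 μmol of weak acid in the vessel, 12.5 mmol/L NaOH titrant, and
piecewise-linear conductivity (slopes −30,000 / +2,000 / +25,000 μS/cm
per L) with optional multiplicative Gaussian noise. The ITC generator
adds a square exothermic binding pulse over the first few injections and a
small constant ion-exchange term to the dilution model. The decay
generator is an exact exponential with optional relative noise. Every
generator records its planted truth and is seeded; identical seeds give
bit-identical output.

## Problem sizes and tolerances used in tests

Default test scenes are 192×192 (pipeline recovery, five images per set)
down to 64×64 (coverage replicates, 40 sets); titration recovery uses the
four planted contents 37/79/186/482 μmol/g with 25 noisy replicates each;
oracle equivalences (bisection vs closed form, loop block-means, ITC mole
bookkeeping) are asserted at 1e−12 relative; end-to-end ratio recovery at
3% (dominated by the ~0.7% ratio-of-Poisson-counts bias at wall
intensities of ~140 counts plus location jitter); noiseless parameter
recovery at 1% (titration) and 0.1% (half-life), noisy titration at 5%.
These sizes keep the full suite under a minute on one CPU while leaving
each tolerance comfortably above the measured estimator spread.

## Known limitations

- The spectral defaults are uncalibrated stand-ins; absolute ratios from
  real cameras will differ, and only comparative/ratiometric conclusions
  transfer.
- The threshold mask is global per image set; gradients in staining or
  illumination would need per-image thresholds or flat-field correction,
  which are out of scope.
- The ITC model treats mixing as instantaneous and complete per
  injection; kinetic broadening of peaks is not modelled (per-injection
  integrated heats are assumed).
- The titration fit assumes exactly three linear regimes; carbonate
  contamination or drifting temperature would violate it.
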