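# aostain

Ratiometric analysis of acridine orange (AO) fluorescence for detecting
early oxidation of wood cell walls, together with the supporting
dye-chemistry computations and synthetic ground-truth data generators.

AO is metachromatic: isolated adsorbed molecules (monomers) emit green,
stacked dimers emit red. On sound softwood, lignin binds AO monomers at
isolated sites (green emission) while carboxyl-bearing polysaccharides
stabilize dimers (red emission). Mild oxidation — by acid chlorite, a
peroxyl-radical initiator, or colonizing decay fungi — removes monomer
binding sites on lignin, suppressing the green emission while leaving the
red largely unchanged. The pixel-wise **red/green ratio** of
dark-subtracted widefield micrographs is therefore a quantitative early
oxidation readout: higher ratio, more oxidation.

The package is aimed at wood-decay and biodegradation researchers who want
to apply or study this ratiometric staining assay, and it implements:

- **`camera_io`** — reading uncompressed 8-bit RGB TIFFs from a linear
  (gamma 1) Bayer-sensor camera; ×2 downsampling by 2×2 block means (the
  sensor tile holds one true chromatic sample per colour); fixed dark-offset
  subtraction.
- **`ratiometrics`** — green-channel threshold masks, pixel-wise R/G ratio
  maps, integer-histogram channel modes, per-image-mean statistics with
  Student-t 95% confidence intervals, percent-change helpers.
- **`photophysics`** — the monomer/dimer association equilibrium
  2M ⇌ D with K = [D]/[M]², solved in closed form
  (2K·m² + m − c = 0), and a linear spectral mixing model mapping
  monomer/dimer emitter densities to camera RGB counts.
- **`calorimetry`** — first-principles modelling and subtraction of the
  AO dimer-dissociation dilution heat from isothermal titration
  calorimetry (ITC) thermograms (fixed K = 3040 L/mol,
  ΔH = −44.4 kJ/mol), plus strong-binding-site accounting and
  Beer–Lambert quantitation (ε = 33,016 L mol⁻¹ cm⁻¹ at 467 nm).
- **`titration`** — Scallan-style three-segment analysis of conductometric
  titration curves; weak-acid (carboxyl) content from the plateau span:
  content = (V₂ − V₁)·c_NaOH / m_sample.
- **`kinetics`** — first-order half-life fits of initiator decay
  (log-linear least squares) and cumulative radical yield
  n·c₀·V·(1 − 2^(−t/t½)).
- **`synthetic_data`** — generators for all four input kinds (micrographs
  with Bayer tiling, dark offset and shot noise; titration curves; ITC
  thermograms; decay series) with machine-readable ground truth, so every
  stage has a round-trip test without instrument data.

## Worked example

Generate a five-image synthetic set whose secondary cell walls carry a
planted R/G ratio of 0.97, then run the full pipeline
(load → downsample → dark-subtract → mask → ratio → summarize):

```python
from aostain.synthetic_data import SceneSpec, generate_image_set
from aostain.pipeline import analyze_set

images = generate_image_set(SceneSpec(seed=7), 5, seed=7, out_dir="demo")
threshold = sum(t.suggested_green_threshold for t in images) / 5
results, summary = analyze_set([t.paths["image"] for t in images], threshold)
print(f"mean R/G ratio {summary.mean_ratio:.3f} "
      f"+/- {summary.ci95_halfwidth:.3f} (95% CI, n={summary.n_images})")
```

which prints

```
mean R/G ratio 0.973 +/- 0.023 (95% CI, n=5)
```

— the planted wall ratio recovered through the camera model, shot noise,
quantization and masking, with a confidence interval whose replication
unit is the image (five "locations"), not the spatially correlated pixels.

The dimerization equilibrium at the reference staining-relevant
conditions:

```bash
$ aostain equilibrium --K 5000 --conc-umol 1000
{
  "K_L_per_mol": 5000.0,
  "c_total_mol_per_L": 0.001,
  "monomer_mol_per_L": 0.00027015621187164243,
  "dimer_mol_per_L": 0.00036492189406417874,
  "fraction_dimer": 0.7298437881283575
}
```

i.e. at 1000 μmol/L total dye and K = 5000 L/mol, 73% of AO molecules are
associated as dimers; at 1 μmol/L the same model gives under 1%.

Other subcommands: `aostain ratio` (image-set analysis to CSV),
`aostain itc-correct`, `aostain titrate`, `aostain decay`,
`aostain radicals`, and `aostain simulate` for the synthetic fixtures.

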