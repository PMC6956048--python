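# corneaquant

Quantification pipeline for ex vivo corneal ectasia studies, with synthetic
ground-truth data generators for every input it consumes.

In enzyme-weakened ("keratoconus-like") corneas and their treatment groups,
four measurements carry the story: collagen fibril density and diameter in
transverse TEM micrographs, Young's modulus from uniaxial strip tests,
collagen denaturation temperature from DSC, and keratocyte/inflammatory gene
expression from qPCR. This package implements each reduction as a tested
library function, and — because such studies rarely deposit raw data — ships
generators that emulate all four raw-data types with known ground truth, so
every estimator can be benchmarked end to end.

## Methods at a glance

* **Fibril density** (`corneaquant.tem`). Micrographs are binarized with an
  adaptive mean-C threshold (foreground where *I < mean_local − C*), fibril
  cross-sections are detected as connected components filtered by area and
  circularity (4πA/P²), and each fibril gets an equivalent-circle diameter
  d = 2√(A/π) · pixel size. Density uses a randomized-window median protocol:
  200 windows of 300 × 300 px per image, ≥ 3 images pooled, density =
  median window count / window area (fibrils/µm²).
* **Young's modulus** (`corneaquant.mechanics`). Engineering stress
  σ = F/(w·t) and strain ε = Δl/l₀; E is the OLS slope of σ(ε) over the
  tangent window [0.7, 0.9] × max strain of the J-shaped curve.
* **Denaturation temperature** (`corneaquant.thermal`). A linear baseline
  through the means of pre- and post-transition windows is subtracted;
  Td is the endotherm peak temperature, refined below grid resolution with a
  Gaussian peak-profile fit.
* **Expression** (`corneaquant.expression`). Comparative Ct:
  ΔCt = Ct_target − Ct_Gapdh, ΔΔCt = ΔCt − mean ΔCt(control), fold = 2^(−ΔΔCt);
  group summaries are geometric means. Student/Welch t tests and one-way
  ANOVA are computed from their defining formulas with p-values via the
  regularized incomplete beta function.
* **Synthetic data** (`corneaquant.synthetic`). Fibril fields are hard-core
  point processes packed by random sequential adsorption and rendered with
  anti-aliased disks, optics blur and detector noise; tensile records follow
  a linear or toe-exponential law on a 0.1 mm/s displacement ramp; DSC traces
  are a linear baseline minus a Gaussian endotherm; Ct tables follow
  Ct = baseline − log2-effect + noise with a stable housekeeping gene.

## Worked example

Run the numbered drivers in order (each prints what it found and writes
tables under `results/`):

```sh
python analysis/01_simulate_inputs.py        # 5-group synthetic dataset
python analysis/02_fibril_density.py
python analysis/03_tensile_modulus.py
python analysis/04_dsc_denaturation.py
python analysis/05_gene_expression.py
python analysis/06_group_statistics.py
```

`02_fibril_density.py` prints, for the default seed:

```
  group  n_images  n_fibrils_detected  density_per_um2  truth_density_per_um2  diameter_median_nm  diameter_iqr_nm
control         3                 504           41.667                 40.054               32.07             6.30
     KC         3                 315           27.778                 25.034               37.70            10.58
    COR         3                 480           38.889                 38.147               28.37             8.71
   CART         3                 453           38.889                 36.001               31.19             7.06
     LN         3                 606           50.000                 48.161               26.12             4.93
```

i.e. the windowed-median estimate tracks the generator's realized density in
every group; the ectatic model (KC) has the sparsest, thickest fibrils and
the lymph-node-treated group the densest, thinnest ones. `03` and `04` then
show the modulus dropping from ≈6.2 MPa (control) to ≈3.7 MPa (KC) and
recovering to ≈5.7 MPa under cornea-particle treatment, with denaturation
temperatures of ≈66.7 °C (control), ≈61.7 °C (KC), restored in all treated
groups; `05` shows Tnfα up ≈5.8-fold in KC and keratocyte markers recovering
to ≈1 after treatment; `06` runs ANOVA plus pairwise t tests on every
endpoint.

The same chain is available as a CLI (`corneaquant simulate|tem|tensile|dsc|
qpcr|stats|run|validate`, each with `--config/--seed/--out`), and
`corneaquant run` executes the whole study and writes a deterministic
`report.json`.

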