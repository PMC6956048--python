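# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Synthetic fibril fields

Transverse TEM sections of corneal stroma show fibril cross-sections as dark,
nearly circular disks with a minimum interfibrillar separation maintained by
proteoglycan bridges. The generator models this as a **hard-core point
process**: diameters are drawn i.i.d. from a lognormal (default; right-skewed,
matching the widened distribution of ectatic corneas) or truncated-normal law
parameterized by arithmetic mean and SD in nm, and centers are placed by
**random sequential adsorption (RSA)** — draw a diameter, draw a uniform
center, accept iff the disk keeps ≥ `min_gap_nm` surface-to-surface clearance
from all accepted disks. Placement stops when the realized count reaches
⌈density × area⌉; an attempt budget of 100 × the target count guards against
infeasible requests, and parameter validation rejects nominal packing
fractions ≥ 0.55 (density × π/4 × (mean diameter + gap)², the regime where
sequential rejection stalls). Neighbor queries use a uniform cell grid, so
generation is O(attempts).

Two deliberate deviations from a textbook RSA:

* **Centers are inset** from the field border by disk radius + 3 blur sigma so
  every rendered disk lies fully inside the raster. Border-clipped disks would
  have unrecoverable truth diameters and would contaminate diameter-recovery
  benchmarks; the inset band is < 1% of the default 2048² px field. The cost
  is a slightly non-uniform intensity within that band.
* **Diameter draws above mean + 6 SD are rejected** so the neighbor-grid cell
  size bounds all interactions. For the default lognormal this truncates
  ≪ 10⁻⁶ of the mass.

Rendering: per-pixel coverage of each disk is approximated by the linear ramp
clip(r + ½ − dist, 0, 1) in pixel units (area-weighted anti-aliasing), which
keeps rasterized disk area unbiased to sub-pixel level; a Gaussian optics blur
(default σ = 0.7 px) and additive Gaussian detector noise (applied after blur,
then clipped to [0, 1]) complete the detector model. Fibrils are darker than
background (defaults 0.2 vs 0.8), as in stained sections.

What the generator does **not** emulate: lamellar 3-D stacking, longitudinal
fibril views, proteoglycan staining texture, uneven illumination, section
folds or debris. Benchmarks passing on these images show the estimators are
correct under the stated image model, not that segmentation would be
artifact-free on real micrographs.

## TEM quantification

* **Adaptive threshold**: foreground where intensity < local mean − offset,
  local mean over an odd square window (default 51 px) with edge-reflected
  padding; a Gaussian-weighted mean is available. The offset default (0.22)
  places the cut near the half-coverage contour of a rendered disk edge for
  the default contrast (0.6), which is what makes equivalent-diameter recovery
  unbiased; for other imaging contrasts the offset should be rescaled
  proportionally. Increasing the offset can only shrink the foreground
  (monotonicity), which the tests assert as a nesting property.
* **Detection**: connected components (8-connectivity default), filtered by
  area ∈ [12, 10 000] px² and circularity 4πA/P² ≥ 0.6 (rejects merged blobs
  and elongated artifacts); circularity is clipped at 1.1 because the
  discrete perimeter estimate can exceed the continuum bound slightly.
  Equivalent-circle diameter is used rather than Feret calipers because the
  cross-sections are near-circular by construction.
* **Density**: window corners are drawn uniformly with replacement on the grid
  of positions where the 300 px window fits entirely inside the image; a
  fibril belongs to a window iff its centroid lies in the half-open square, so
  abutting windows never double-count. 200 windows per image, ≥ 3 images; all
  per-window counts are pooled and the **single pooled median** divided by the
  window area is the density (a per-image-median variant exists behind a
  flag). The median is integer-valued (or half-integer), so at sparse
  densities the estimate is quantized: with an expected window count λ ≈ 3.6
  the nearest attainable estimates are ±14% apart, which is why the recovery
  benchmark tolerates 2/20 misses at the sparse end of 10–100 fibrils/µm².
  Fibrils with centroids in the image are counted regardless of border
  clipping; no guard-frame correction is applied, and the resulting edge bias
  (fraction of fibrils within a radius of the border, < 1% at default
  geometry) is accepted rather than corrected.

## Tensile reduction

Engineering stress and strain throughout (no cross-section updating — strip
geometry is measured once). The synthetic law is either linear (σ = Eε) or
toe-exponential (σ = A(e^{rε} − 1)), the standard phenomenological form for
fibril recruitment; defaults A = 0.05–0.06 MPa, r = 8, max strain 0.4 give
tangent moduli of 3–6 MPa at high strain, the plausible range for swollen
ex vivo corneal strips. The modulus estimate is the OLS slope over strain ∈
[0.7, 0.9] × max strain. For a convex curve this equals the mean tangent over
the window up to a relative bias ≈ (rw)²/60 (w = window width in strain),
≈ 0.7% at defaults — hence the 2% benchmark tolerance. The gauge length has
no protocol default and is a required input.

## DSC reduction

The thermogram model is heat flow = linear baseline − Gaussian endotherm
(endotherm-down convention; a switch handles exo-down instruments). Detection:

1. baseline fit through the mean heat flow of a pre- and a post-transition
   window (defaults: first and last 10% of the 10–95 °C scan); this leaves
   both window means at exactly zero after subtraction;
2. peak located as the argmin of the residual **after light smoothing**
   (Gaussian, σ = 3 samples) — without it, a single noise spike on a shoulder
   can win the argmin and collapse the half-height span;
3. no-peak guard: residual extremum must exceed 3 × the noise level (1.4826 ×
   MAD of the residual inside the baseline windows);
4. sub-grid refinement by fitting −depth·exp(−(T−c)²/2s²) to the raw residual
   within ±2.5 estimated sigmas of the peak (quadratic vertex and 3-point
   parabola as fallbacks). Td is the fitted center — peak temperature, not
   onset.

Because the refinement depends only on the baseline-subtracted residual and
the baseline windows sit ≫ 5 sigmas from the peak, Td is invariant to the
baseline slope to < 10⁻⁶ °C on noise-free traces. Known limitation: at a
peak-to-noise SNR of exactly 10 with peak σ = 2 °C and 0.1 °C sampling, the
center estimate's statistical floor is ≈ 0.05 °C (Cramér–Rao), so the
fraction of single scans recovered within 0.1 °C hovers at 94–98%; the
benchmark ensemble draws SNR uniformly from [10, 30], where the rate is
comfortably ≥ 95%. Multi-peak deconvolution and enthalpy integration are out
of scope.

## Expression and statistics

The comparative-Ct model assumes equal (perfect) amplification efficiency for
target and housekeeping gene; no Pfaffl-style efficiency correction is
applied. ΔΔCt is taken against the **mean control ΔCt per gene**, which makes
the control group's geometric-mean fold exactly 1 and the housekeeping fold
exactly 1 per sample — both asserted as exact identities in tests. Group
summaries are geometric means with SDs on the log2 scale, the appropriate
scale for ratio data. Per-sample plate shifts cancel in ΔCt, which the tests
assert as an invariance.

Student (pooled, df = n₁+n₂−2) and Welch (Welch–Satterthwaite df) t tests and
one-way fixed-effects ANOVA are computed from their defining formulas;
two-sided p-values come from the regularized incomplete beta function
(p = I_{ν/(ν+t²)}(ν/2, ½) and the analogous F form) rather than table lookups
or library test calls — the library implementations (scipy, statsmodels)
appear only as independent oracles in the test suite. Degenerate inputs
(zero variance everywhere with equal means; all-identical ANOVA groups) raise
a dedicated error rather than returning NaN. The reporting pipeline runs
ANOVA across all five groups plus pairwise Student t tests against control
and against the ectatic model group, with no multiple-testing correction by
default (a Holm adjustment is available but off, matching common practice in
this literature).

## Study presets and problem sizes

The shipped five-group preset (control, KC, COR, CART, LN) encodes only the
**ordinal** structure of the measured contrasts: KC least dense
(25/µm²), thickest (38 ± 8 nm) and softest; LN densest (48/µm²) and thinnest
(26 ± 4 nm); COR restoring the modulus to within ~10% of control. Absolute
densities and diameters are design choices on a benchmarkable scale, since
the source measurements are graphical only; denaturation temperatures use the
reported group means and SDs (66.80/62.57/66.96/66.08/66.80 °C). Expression
effects put Tnfα up 2.5 log2 in KC and slightly below control after
treatment, and keratocyte markers (Aldh, keratocan, biglycan) down 1.2–1.5
log2 in KC, restored after treatment, with 0.25-cycle Ct noise at n = 6.

Default problem sizes were chosen so the full test suite and the acceptance
script each run in minutes on one core: 1024² px micrographs (2 nm/px) in the
pipeline and analysis drivers, 2048² px in the recovery benchmarks, 20-field
density sweeps, 100-scan Td ensembles, 10 000-replicate null calibrations and
20-replicate ordering checks. All randomness flows from one global seed
through CRC-hashed per-stage substreams (`corneaquant.seeding.derive_seed`),
so any stage can be rerun independently and reproducibly; no stage reads OS
entropy.
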