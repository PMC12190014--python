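# Methods

## Radiometrics

All activities are kept in Bq internally; percent scales appear only at
reporting boundaries. Decay correction uses
A(reference) = A(measured)·2^(Δt/T½) with Δt the time elapsed since the
reference; the operation is its own inverse under negation of Δt. The
decay reference is the **injection time** for both image and
gamma-counter data, which makes %ID a conserved fraction of the
administered dose. The default half-life is the Cu-64 physical constant
(12.7 h) and is overridable per injection context for other isotopes.

%ID/ml is 100·c̄/A₀ for a decay-corrected mean concentration c̄ (Bq/ml)
and injected activity A₀. For ex vivo counting, the dose standard is
modelled as a known *fraction* of the injected dose counted under the
same conditions as the organs, rather than an absolute detector
calibration; %ID/g is then 100·(net/(standard/fraction))/mass. Because
the standard is an aliquot of the same decaying dose, the %ID/g ratio is
invariant to the choice of decay reference; both injection-time
(default) and counting-time references are supported.

Background correction subtracts the uptake measured in antigen-negative
(wild-type) animals and deliberately does **not** floor at zero:
negative specific uptake is returned with a `below_background` flag so
downstream correlations are not censored.

The bead-assay immunoreactive fraction is (BS − S)/(BS + S), where BS is
the beads-plus-half-supernatant tube and S the half-supernatant tube; it
lies in [−1, 1] and equals 1 only when no free tracer remains.

## Core/margin geometry

"50% of the tumor diameter" is implemented as an affine contraction of
the tumor contour about its centroid by a factor `scale` (default 0.5)
per axis, not as area-based erosion: contraction matches the diameter
convention, is shape-general, and gives a core of `scale²` of the tumor
area for convex 2D shapes (25% at the default). Rasterization uses the
pull-back rule — a voxel center x belongs to the core iff
centroid + (x − centroid)/scale lies inside the original mask — which is
canonical for star-shaped regions and reduces exactly to index space,
so anisotropic voxel spacing cannot bias the core shape (contraction is
defined in physical mm). Masks are voxel-center based throughout: a
voxel belongs to a region iff its center does.

The default analysis mode is a single centered axial cross-section
(`slice2d`): the slice is the axial index nearest the mask's center of
mass, and core/margin partition the tumor's area on that slice. A full
3D mode (`volume3d`) applies the same contraction along all axes. The
margin is always the set difference tumor ∖ core, so the partition
identity (whole-tumor mean = size-weighted core/margin means) holds to
float tolerance by construction. A contraction that empties the core
(tiny tumors relative to the grid) raises a diagnostic error rather
than returning an empty region.

## Decision rules

Therapy stratification is `ratio > 1.3 → continue monotherapy`, with a
**strict** inequality: a ratio of exactly 1.3 adds the combination
antibody. The growth-responder rule is V(d7)/V(d0) < 1; a ratio of
exactly 1 is called nonresponder — the two defining predicates (< 1 and
> 1) leave the boundary open, and the conservative assignment is used.
Reported rates are rounded half-away-from-zero to integer percent
(matching how such rates are conventionally printed) while exact
fractions are retained in all outputs.

Spatial pattern calls take a signal floor `u_min` plus ratio cut-offs
`r_hi` (default 1.3) and `r_lo` (default 1/1.3 ≈ 0.77, the symmetric
reciprocal): deserted when both regions are below the floor, enriched
when the core is above the floor and the ratio exceeds `r_hi`, excluded
when the margin is above the floor and the ratio is below `r_lo`,
indeterminate otherwise. The classes are qualitative in origin, so
every call carries a full rule trace (each threshold comparison and its
outcome) for auditability. `u_min` defaults to 0.3 %ID/ml, the scale of
antigen-negative background uptake; studies should override it with the
median whole-tumor uptake of their own background group.

## Histology

The invasive margin is the **exterior** band obtained by dilating the
tumor core by the margin width (default 100 μm) in physical units and
subtracting the core, computed via a Euclidean distance transform with
the pixel spacing as sampling; murine "marginal areas" are mapped onto
the same construct for cross-species comparability (an approximation —
interior rims are not modelled). Cell membership uses nearest-pixel
containment of the centroid, with core tested before margin so shared
boundaries resolve to the core.

Densities are emitted both as cells/mm² and, when field counts are
given, cells/HPF; the HPF area default is 0.237 mm² (a standard 40×
field) and configurable, since field area is microscope-dependent.
Fewer than 10 counted fields triggers a warning, not an error. The
CD3⁺CD8⁻ CD4 proxy carries a QC verdict — pass when double-negative
(CD3⁺CD4⁻CD8⁻) cells are under 10% of CD3⁺ cells — and failing samples
are flagged, never dropped (exclusion is a caller decision, since the
check argues validity rather than filtering).

## Statistics

Unpaired comparisons default to the Welch unequal-variance t test
(group sizes in such studies typically differ); the pooled Student form
and paired tests are available per recipe. Zero-variance degenerate
comparisons are flagged rather than raised, so panels keep running.
The Holm–Šídák step-down is implemented directly —
p̃₍ᵢ₎ = max₍ⱼ≤ᵢ₎ min(1, 1 − (1 − p₍ⱼ₎)^(m−j+1)) on the sorted
sequence, returned in input order — because it is the multiplicity
backbone of the reporting layer; the test suite cross-checks it against
statsmodels' implementation. ANOVA is delegated to the host ecosystem
and not re-derived. Stars use p ≤ 0.05/0.01/0.001.

## Synthetic data

The generators emulate every input the pipeline assumes, so all stages
are testable without any download, and every generator returns its
ground truth alongside the data.

* **PET phantoms** — a spherical tumor (default radius 4 mm) on a
  49³ grid at 0.5 mm isotropic spacing; the odd grid centers the sphere
  on a voxel so the scale-0.5 pull-back maps voxel centers to voxel
  centers and noiseless core/margin recovery is rasterization-exact.
  The true core uses the same pull-back geometry as the analysis.
  Canonical pattern contrasts (in %ID/ml-equivalent): uniform 0.4/0.4,
  enriched 0.6/0.3, excluded 0.2/0.5, deserted 0.1/0.1, background
  0.05 — anchored to the ~0.2–0.6 %ID/ml range such tracers show in
  tumors. The PSF is an isotropic Gaussian (default σ 0.8 mm as a
  preclinical-resolution surrogate; 0 disables). Noise is Poisson on
  expected counts (`noise_scale` counts per voxel per %ID/ml) converted
  back to concentration — the simplest model consistent with PET count
  statistics; scatter, attenuation and reconstruction artefacts are not
  simulated, so passing recovery tests bound rasterization and counting
  noise only, not reconstruction bias on real scanners.
* **Gamma records** — organ fractions of the dose with masses and a
  counting delay; constructed so %ID/g recovery is exact at zero noise,
  with optional Poisson counting noise.
* **Cell patterns** — homogeneous Poisson placement per region (disk
  core, default radius 500 μm; exterior margin band) at stated
  densities, with FoxP3 Bernoulli-thinned onto CD4 cells at the Treg
  fraction. Real tissue is clustered and anisotropic; the homogeneous
  model tests counting and geometry, not clustering robustness.
* **Growth cohorts** — exponential growth/regression (defaults
  k = −0.05/day responders, +0.08/day nonresponders, so V7/V0 ≈ 0.70
  and 1.75) with multiplicative lognormal measurement noise (σ = 0.10).
* **Guided trial** — latent responder prevalence (default 0.4 in a
  21-subject cohort, matching the scale of the guided experiment), a
  day-5 ratio drawn lognormally per class (medians 1.8/0.9, σ = 0.25,
  i.e. sensitivity and specificity ≈ 0.9), threshold stratification,
  and combination rescue of stratified nonresponders with probability
  0.7. The closed forms for sensitivity/specificity are exposed on the
  spec for Monte-Carlo checks.

Reproducibility: identical seeds give bit-identical output; a root seed
plus documented per-stage offsets (`stage_seed`) keeps end-to-end runs
reproducible while stages remain independently seedable.

## Pipeline and I/O

Volumes and masks are NIfTI-1 on identical grids; a grid mismatch is an
error naming the offending pair — never a silent resample. Tables are
CSV with documented columns (metadata: `subject_id`,
`injected_activity_Bq`, `injection_time`, `scan_time`; cells: `x_um`,
`y_um` plus 0/1 marker columns; growth: `subject_id`, `day`,
`volume_mm3`); reports are additionally emitted as JSON. Every output
row carries the config hash and seed, so re-runs on identical inputs
are byte-identical. The CLI (`quantify`, `stratify`, `histo`,
`simulate`, `report`) is a thin layer over the library; a flat YAML
config supplies defaults and flags override.

## Problem sizes and numerical choices

The bundled property suites use 49³ phantoms, 100-seed Monte-Carlo
means for ratio recovery (Poisson noise at ≥100 expected counts per
voxel), 50 random phantoms for the partition identity, 10⁴ cells for
assignment conservation, 1,000 random p-vectors (m ≤ 10) for the
step-down oracle, and 200 trial replicates — sizes chosen so
Monte-Carlo error sits well inside the asserted tolerances while the
whole suite runs in seconds. Ties in stratification and responder
rules are resolved as documented above; empty margins yield a NaN ratio
with an `undefined_ratio` flag rather than an exception, and such
subjects are unassignable by the stratifier.

## Known limitations

Tumor and organ masks are taken as given (no segmentation or
registration); DICOM, PET reconstruction, detector dead-time and
attenuation correction, and upstream cell segmentation are out of
scope. The margin construct assumes the core mask's exterior is tissue;
section edges are not handled specially. The phantom family is
spherical — the geometry code accepts arbitrary star-shaped masks, but
the generators do not exercise lobulated tumors.
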