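# Methods

## Scope and model

`smearmsi` operationalizes a single-cell MALDI-TOF mass-spectrometry-imaging
(MSI) workflow for blood smears: per-pixel mass spectra acquired on a
rectangular raster over a smear are reduced to a feature matrix, cell regions
(RBC, WBC) are compared against plasma-remnant background regions feature by
feature, and the differential m/z are annotated with adduct-resolved
metabolite matches. Because no public raw data accompanies the study design
this package follows, a first-class simulator generates rasters with known
ground truth so that every stage — and the pipeline end to end — is testable.

## Adduct arithmetic (`chemmass`)

Monoisotopic masses are sums of most-abundant-isotope masses over a fixed,
versioned element table (CODATA/IUPAC values, bundled as
`data/element_masses.csv`; H, C, N, O, P, S, Fe, Na, K, Cl, Se, Mo, I plus
proton and electron). Ion m/z of a neutral species M follows

    m/z = n·M + Δ

for the singly charged adduct `nM±species…` (species ∈ {H, Na, K, Cl, H₂O}).
The default mass convention is **atomic**: protonation adds the H *atom*
mass (1.00783 Da) and no electron-mass correction is applied. The
ion-physics convention (proton mass, electron bookkeeping) is available via
`electron_correction=True`; the two differ by ≤ 0.0011 Da, negligible
against the 0.025 Da matching tolerance. Neither convention reproduces all
four published marker ion m/z at three decimals simultaneously — the printed
table mixes conventions (its Fe(II) heme [M−H]⁻ value implies proton-mass
subtraction while its sodiated IMP value implies the atomic convention) —
so the package standardizes on the atomic convention and documents that the
Fe(II) heme ion computes to 615.169 vs the printed 615.170.

A historical spelling quirk is accepted: `M-H20-H` (digit zero) parses as
`M-H2O-H`. The bare rule `M` denotes the radical/intact cation (oxidized
heme) and is positive by convention.

## Data model and I/O (`msidata`)

Pixels are 0-based `(i, j)` with the physical frame anchored at the grid
corner; pixel centers sit at `((i+0.5)·pitch_x, (j+0.5)·pitch_y)` µm.
ROIs are labeled ellipses (RBC/WBC/plasma) in the same frame; membership is
by **center containment** under the rotated-ellipse inequality — the
simplest deterministic rule at ~8 µm pitch, where area-overlap weighting
would add complexity without changing which spectra are pooled. Datasets
round-trip through imzML (continuous or processed binary mode, float64 both
axes, hence lossless) with a JSON sidecar for raster metadata imzML does not
standardize (pitch, polarity, matrix/setting labels, m/z window).

The metabolite database is a frozen table, not a live query: bundled is one
record per metabolite in the published differential report plus the ATP and
IMP quality markers (42 records), with literature formulas and masses
computed from them. Three caveats are frozen into the table's provenance
rather than silently corrected:

* thiamin diphosphate is stored as the neutral conjugate C12H18N4O7P2S of
  the KEGG cation formula;
* cervonoyl ethanolamide (C13828) and molybdate (C06232) do **not** verify
  against their printed m/z at ±0.025 Da under any sensible formula (both
  are ≈2 H off); they are retained with their literature formulas and
  excluded from round-trip annotation checks;
* the source prints no HMDB accessions, so the `hmdb_id` column carries
  KEGG-derived placeholder identifiers (annotation uniqueness operates at
  metabolite level, so this is inert).

## Simulator (`synthetic_smear`)

Each smear is a raster at the D0 (8×7 µm) or D1 (8×6 µm) pitch. RBC
(~7 µm) and WBC (~12 µm) disks are placed by rejection sampling without
overlap, centers snapped to pixel centers — at this pitch a blood cell is a
one-pixel object, and snapping guarantees every cell ROI contains its pixel.
Biconcave RBC geometry is ignored; morphology is irrelevant to the spectral
pipeline.

Per-pixel profile spectra are sums of Gaussian peaks sampled at 7 points
across ±3σ:

* **Markers** (published ion m/z): negative mode — ATP [M−H]⁻ 505.988
  (enriched in RBC and WBC) and Fe(II) heme [M−H]⁻ 615.170 (RBC); positive
  mode — IMP [M+Na]⁺ 371.037 and Fe(III) heme [M]⁺ 616.177 (RBC). Default
  enrichment factor 5.
* **Plasma background**: easily ionized free fatty acids and phospholipids
  (negative) or LPC/PC/SM species (positive), enriched 3× in plasma
  remnants and present at a low level under cells as well.
* **Fillers**: 650 class-neutral peaks per window with log-normal
  amplitudes, drawn on a 0.1 Da candidate grid (keeps peak supports
  disjoint) — enough candidates that the top-500 cap binds.

Noise model: per-pixel multiplicative log-normal TIC factor (σ = 0.25),
additive half-normal baseline per sample point (σ = 0.02 in amplitude
units), and per-(donor, peak) log-normal random effects (σ = 0.15) so a
cross-donor test faces realistic between-sample variance. The peak width
(σ = 0.01 Da, so a 0.020 Da bin captures one peak) and all noise scales are
package choices — the source publishes neither SNR nor peak width — and are
exposed in `SmearSimConfig`.

A study is 6 donors × (optionally two m/z windows, 200–600 and 600–900 Da)
with one ROI design per smear: 5 RBC + 1 WBC + 3 plasma ellipses. The peak
panel is shared across donors (same assay, same compounds); cell layout,
donor effects, and noise are per-donor, all derived from one seed via
`SeedSequence` spawning.

**`null_mode`** is the calibration switch: it forces every class-enrichment
factor to 1 *and* the donor-effect σ to 0. Rationale: the type-I check asks
whether the testing machinery holds its nominal level, which is a
mathematical property only when ROIs are exchangeable iid draws. With donor
random effects retained, the balanced design makes the Welch test
*conservative* by construction (donor effects cancel exactly in the group-
mean difference but still inflate the variance estimate) — a real and
interesting phenomenon, but a different experiment than calibration.

What the simulator does **not** emulate: LASER ablation physics, matrix
crystal heterogeneity, oversampling spot overlap, ion suppression, mass
drift or calibration error, isotope patterns. Passing tests therefore show
the *analysis chain* is correct and calibrated under its stated assumptions,
not that real smears meet those assumptions.

## Preprocessing (`preprocess`)

Per pixel: TIC normalization (all-zero pixels are excluded and reported,
never imputed). Per dataset: centroid binning on half-open 0.020 Da bins
anchored at the window's lower bound (200 or 600 Da); a point exactly on an
edge goes to the upper bin; per-bin intensity is the sum of member
intensities (binning conserves total intensity exactly) and the centroid is
the intensity-weighted mean m/z. Bins are kept only if greater than 0.1% of
the reference maximum, then the 500 most intense survive.

Two readings of the published recipe are deliberately disambiguated:

* "highest signal in the mass spectrum" → the maximum of the
  **pixel-averaged** TIC-normalized spectrum (default; the average spectrum
  is what a practitioner inspects). `reference="pixel_max"` uses the highest
  single-pixel bin instead.
* "500 most intense" → ranked by **mean** intensity across pixels (default);
  `ranking="max"` available. Ties break toward the lower m/z.

Observed m/z entering annotation are intensity-weighted bin centroids, not
bin centers.

## Ion images (`imaging`)

An ion image is the per-pixel sum of TIC-normalized intensities within
±0.025 Da (inclusive) of the target. Display processing mirrors the named
vendor chain with documented choices where the vendor internals are
unpublished: median smoothing (3×3, reflected edges) and separable
Lanczos-3 upsampling with per-sample weight renormalization (constants map
to constants) and reflection padding, clipped at 0. Overlays alpha-blend
the intensity colormap over the synthetic cell-label map, which stands in
for the co-registered light-microscopy underlay.

## Differential expression (`differential`)

The sampling unit is the **ROI**, not the pixel: pixels within one cell are
not independent draws from the donor population, and pooling them would
pseudo-replicate. Each ROI contributes the arithmetic mean of its member
pixels' feature vectors. Features are matched across donors by bin index;
a feature absent from one donor's top-500 is zero-filled there. Each m/z
window is tested separately and significant m/z are unioned afterwards.

The test is Welch's unequal-variance two-sample t (group sizes 30/6/18
under the default design; variances unknown), two-sided, at a raw 0.05
limit with no multiple-testing correction — matching the published
procedure; pooled-variance and Benjamini–Hochberg variants sit behind
flags. Degenerate inputs: both groups constant and equal → t = 0, p = 1;
both constant and unequal → ±∞, p = 0; groups of one → error. Fold change
is mean(cell)/mean(plasma), flagged infinite when the plasma mean is 0.

## Annotation (`annotate`)

Exhaustive scan over (metabolite, adduct rule) pairs, polarity-gated
(negative: M−H, 2M−H, M−H₂O−H, M+Cl; positive: M, M+H, M+Na, M+K, 2M+H,
2M+Na, 2M+K, M+H−H₂O, M+H−2H₂O, 2M+H−H₂O — exactly the adduct vocabulary
of the source tables); hit iff |observed − theoretical| ≤ 0.025 Da
(inclusive). Filtering: drop metabolites without KEGG id or the
endogenous/essential flag; keep an observed m/z only when exactly **one
metabolite** remains. Uniqueness at metabolite level (not per adduct):
one compound explained by two adducts is still a single hit, with the
smaller-|error| adduct reported. The published heme row (m/z 616.17073,
printed adduct M+H) resolves through the bare-cation rule [M]⁺ — the
printed adduct is inconsistent with the printed m/z by ~1 Da and is kept
as-is in the bundled report table.

## Problem sizes and numerical checks

Simulation-based checks run at desk scale, chosen once: 24×24-pixel grids
per donor for calibration and power experiments (the ROI means are the
sampling unit, so grid size beyond ROI coverage is statistically inert) and
32×32 for worked examples. The type-I experiment uses 200 replicate null
studies × 500 features (6 donors each) and compares the mean flagged
fraction to 0.05 within 3 binomial standard errors; the recovery experiment
uses 10 replicate studies at 5× enrichment across both m/z windows and
requires every truth pair recovered in ≥ 90% of replicates. Binning and
annotation are additionally checked against brute-force reference
implementations on randomized small instances.

## Known limitations

* The simulator's Gaussian, drift-free peaks make binning essentially
  lossless; real TOF data would exercise centroiding and tolerance choices
  harder.
* The published differential counts and fold-change values depend on the
  authors' raw donor data, which is available only on request; this package
  reproduces the *procedure* and output schema, not those numbers.
* Ion images are rendered per dataset without cross-dataset intensity
  scaling; comparisons across settings are qualitative.
* All ions are treated as singly charged; no isotope-pattern or MS/MS
  evidence enters annotation, so "unique hit" means unique within the
  bundled table at ±0.025 Da, not a confirmed identity.
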