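# smearmsi

Single-cell MALDI-TOF mass spectrometry imaging (MSI) analysis of blood
smears: simulation with ground truth, spectral preprocessing, differential
m/z expression between blood cells and plasma remnants, adduct-resolved
metabolite annotation, and ion-image rendering.

## The problem

A blood smear on a conductive slide, imaged by MALDI-TOF MSI at ~8 µm
raster pitch, yields one mass spectrum per pixel — fine enough to assign
spectra to individual red and white blood cells (RBC, WBC). Two questions
follow: *which m/z are differentially expressed between a cell type and the
plasma-remnant background*, and *which metabolites do those m/z belong to*?
This package implements that analysis chain for anyone building or
evaluating single-cell blood-smear MSI workflows, with a simulator that
stands in for raw data (which, for this study design, exists only on
request) so that every stage is testable and its statistics auditable.

## The method

For each pixel spectrum, intensities are TIC-normalized
(`x_i ← x_i / Σ_j x_j`) and reduced to centroids on half-open 0.020 Da
bins anchored at the acquisition window's lower bound; per bin, intensity
is the sum of member intensities and the centroid is their
intensity-weighted mean m/z. Bins ≤ 0.1% of the maximum of the
pixel-averaged spectrum are dropped and the 500 most intense bins are kept.

Spectra are pooled by region of interest (ROI): 5 RBC, 1 WBC, and 3
plasma-remnant ellipses per smear, from 6 donors (30/6/18 samples). Each
feature is tested cell-vs-plasma with Welch's two-sample t-test,

    t = (x̄_c − x̄_p) / √(s²_c/n_c + s²_p/n_p),

two-sided, raw α = 0.05, and the fold change x̄_c/x̄_p is reported.
Significant m/z are matched against a frozen metabolite table over a
polarity-gated adduct vocabulary (M−H, 2M−H, M−H₂O−H, M+Cl; M, M+H, M+Na,
M+K, 2M+H, 2M+Na, 2M+K, M+H−H₂O, M+H−2H₂O, 2M+H−H₂O), where an adduct ion
of neutral mass M has m/z = n·M + Δ; a match requires
|observed − theoretical| ≤ 0.025 Da, and only *single* hits with a KEGG id
and the endogenous/essential attribute are reported. Ion images are ±0.025
Da window sums, median-smoothed and Lanczos-upsampled for display.

The simulator generates smears (non-overlapping RBC/WBC disks on a plasma
background) whose spectra contain cell-type-enriched marker peaks at the
published quality-indicator ion m/z — ATP [M−H]⁻ 505.988, heme Fe(II)
[M−H]⁻ 615.170, IMP [M+Na]⁺ 371.037, heme Fe(III) [M]⁺ 616.177 — a
plasma-lipid background, hundreds of filler peaks, multiplicative TIC
variation, additive baseline noise, and per-donor random effects. See
`docs/methods.md` for the model, parameter defaults, and design decisions.

## Worked example

Simulate a 6-donor study (32×32 pixels per smear, D1 negative mode, both
m/z windows) and run the whole chain:

```sh
smearmsi run --seed 42 --grid 32 32 --n-donors 6 -o out/
```

prints

```
done: significant RBC=20 WBC=18; 6 annotated; truth recovery 19/19
```

meaning: of the 1000 features (500 per window), 20 were flagged
differentially expressed for RBC and 18 for WBC at α = 0.05; 6 significant
m/z received a unique metabolite annotation; and all 19 ground-truth
enriched/depleted (m/z, cell type) pairs were recovered with the fold
change on the correct side of 1. `out/annotations.csv` begins

```
mz,adduct,kegg_id,metabolite,cell_plasma_ratio,setting,cell_type,mass_error
505.99178...,M-H,C00002,Adenosine triphosphate (ATP),4.989...,D1,RBC,0.0039
615.17378...,M-H,C00032,Heme,5.003...,D1,RBC,0.0043
```

— the ATP and heme marker bins, recovered at fold change ≈ 5 (the
configured enrichment) and annotated through the M−H rule within a few mDa.
`out/` also holds the per-feature differential tables, the ROI sample
table, the truth-recovery report, rendered ion-image overlays, and a
manifest with the config hash (reruns are byte-identical).

The same stages are available singly (`smearmsi simulate`, `preprocess`,
`image`, `diff`, `annotate`) and as library functions
(`smearmsi.generate_study`, `build_feature_matrix`, `differential_table`,
`match_mz`, ...).

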