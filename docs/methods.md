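# Methods

This note documents the models, defaults and numerical choices behind
`hippospec`, and what the synthetic phantoms do and do not establish about
real tissue data.

## Band integration with trapezoidal baseline

A biochemical parameter is the baseline-corrected integrated absorbance of
one band or massif over a closed window `[lo, hi]` (cm⁻¹), or the ratio of
two such integrals. The baseline is the straight line through two anchor
points, one per window edge. Each anchor is computed from the channels
within ± the anchor half-width of the edge, as the pair *(mean wavenumber,
mean absorbance)* of those channels. Anchoring at the mean wavenumber of
the actual channels — not at the nominal edge — makes the subtraction
annihilate affine spectra *exactly*, channel grid notwithstanding; this is
the property that lets instrument baseline offset and linear drift cancel
out of every parameter. The corrected spectrum is integrated with the
trapezoid rule over the channels inside the window. Negative corrected
areas are retained and flagged rather than clipped: silent clipping would
bias group means upward in low-signal regions. Peak-height mode
(max of the corrected spectrum in-window) is available because "band
intensity" is reported ambiguously across the literature; area is the
default.

**Window defaults.** Integration limits in vendor mapping software are instrument- and
operator-specific and rarely published, so the defaults are conventional:
single bands use a ±24 cm⁻¹ window around the nominal center, the two
massifs use their conventional ranges (2800–3000, 1360–1480 cm⁻¹), and the
amide-I sub-bands (1635, 1658 cm⁻¹) use ±8 cm⁻¹ so their windows stay
disjoint. Anchor half-width is 8 cm⁻¹, except ±4 cm⁻¹ for the two
sub-bands: an 8 cm⁻¹ anchor on an 8 cm⁻¹ half-window reaches into the
neighbouring sub-band's flank and leaks its amplitude into the baseline,
which would couple the 1635 and 1658 estimates. Every limit is overridable
through a YAML registry file (`bands.registry_from_yaml`), so
instrument-specific limits can be dropped in without code changes.

**Registry.** The default registry holds 17 parameters: the six absolute
intensities (1658, 2800–3000, 1080, 1240, 1360–1480, 1740), the two
structural ratios (1635/1658 β-sheet-to-α-helix, 2924/2955 CH₂/CH₃) and
nine compound ratios of the absolute bands against amide I and the lipid
massif.

**Ratio guard.** Ratio pixels whose denominator magnitude falls below
1e-3 AU·cm⁻¹ are marked invalid (value 0, validity flag false) and are
excluded from all downstream statistics; no NaN/Inf ever enters a chemical
map.

## Layer statistics

Per-layer pixel populations are taken from an integer label mask after
morphological erosion of the layer region with a 4-connected cross
(default radius 1 pixel, image borders count as outside). This is the
programmatic counterpart of the manual practice of avoiding pixels on
layer borders; at ~25 μm pixels one erosion step removes roughly one cell
body's width. Pixel values are averaged to one value per animal × layer ×
parameter; group tests always run on per-animal means, never on pixels
(pixel-level testing would pseudoreplicate). QC minima default to 120
(GR), 150 (PY) and 300 (MU, MO) pixels — the last an interpretation of
"several hundred" — and animals failing a minimum are excluded from that
layer's comparisons and listed in the run report.

The Mann–Whitney *U* test is two-sided by default. With both samples ≤ 9
and no ties the p-value is exact (enumeration of rank assignments via
scipy's exact method); otherwise the normal approximation with tie and
continuity corrections is used. If every value in both samples is
identical the test is degenerate and reported as p = 1 with direction
"none". Significance uses raw p < α (default 0.05) per comparison,
matching a per-comparison 5% design; a Benjamini–Hochberg adjusted column
is reported for transparency but does not drive the flag. Direction is the
sign of the first group's median minus the second's.

Subgroup comparisons pair severe-vs-control, light-vs-control and
severe-vs-light; intermediate tiers (ICS) are deliberately left out of the
pairwise tables.

## Behavioral clustering

Features per animal and seizure type: cumulative intensity (sum of the
daily scores over the 21-day protocol) and cumulative duration (s). The
two features are z-scored before clustering by default — intensity scores
and seconds are incommensurate, and raw Euclidean geometry would be
dominated by duration. A raw-feature flag exists because analyses of this
design often leave standardization unstated.

Ward linkage is implemented as the Lance–Williams recursion. The default
dialect (`ward.d`) applies the Ward update directly to squared Euclidean
distances — the "classic" convention of legacy statistics packages, whose
merge heights are in squared-distance units. The `ward.d2` dialect (on
distances) is available by flag and is cross-checked against
`scipy.cluster.hierarchy.linkage(..., "ward")` in the test suite.
Minimum-distance ties are broken by the lexicographically smallest cluster
id pair, making merge order fully deterministic; identical feature vectors
therefore cluster reproducibly (with a warning). Cluster counts are fixed
by design — k = 3 for clonic (CS/ICS/LCS), k = 2 for tonic (TS/LTS) — and
severity labels are assigned by descending cluster-mean cumulative
intensity, ties broken by smallest member index.

## Synthetic phantoms

A phantom emulates a transflection FT-IR map of a hippocampal section:
a 48 × 50 pixel image with a 2-pixel background margin and four horizontal
layer stripes (MO/GR/PY/MU at 13/8/8/15 of 44 tissue rows — enough that
every layer clears its QC minimum after 1-pixel erosion), on a 900–4000
cm⁻¹ axis at 4 cm⁻¹ spacing (a 2× finer digitization of the 8 cm⁻¹
instrument resolution).

Each layer's noiseless spectrum is a sum of Gaussian bands (Lorentzian
available) at 1080, 1240, 1400, 1455, 1545, 1635, 1658, 1740, 2850, 2924,
2955 and 3290 cm⁻¹, with amplitudes reflecting the broad compositional
contrast between cell-body layers (GR, PY: more nucleic acid/protein) and
neuropil (MU, MO: more lipid). Stochastic ingredients, all driven by one
seed:

| ingredient | default | rationale |
|---|---|---|
| additive pixel noise | σ = 0.005 AU, i.i.d. Gaussian | typical FT-IR rms noise scale |
| baseline drift | per-pixel quadratic, coeff. σ = 0.01 AU | smooth offset/slope/curvature; the affine part is exactly removed by the baseline |
| animal band scatter | lognormal σ = 0.05 per layer × band | between-animal biological variability (~5% CV); drawn independently per layer so layer-wise tests are not artificially coupled |
| section thickness | lognormal σ = 0.05 global | multiplicative path-length variation; cancels in ratios |

Group × layer anomalies are planted as multiplicative factors on band
amplitudes. The default effect map encodes the direction pattern
characteristic of the kindling model — raised β-sheet component in MO,
raised 1080 in GR+PY, lowered 1240 in MU+MO, raised 1740 and lowered
1360–1480 massif in all layers, raised lipid massif in PY — at ±15%.
The magnitudes are free parameters of the generator, not measured values:
published reports of this model give significance patterns (box-plot
annotations), not effect sizes.

**Ground truth** per phantom is the closed-form truncated-Gaussian area of
each registry band (error-function truncation to the integration window,
no baseline, no cross-talk), evaluated at the animal's realized
amplitudes. Planted multiplicative effects therefore appear *exactly* as
ratios of ground-truth values, which is what the recovery tests exploit.

**Idealizations.** The amide-I sub-bands use σ = 2.5 cm⁻¹ — far narrower
than real protein bands (FWHM ~40 cm⁻¹) — so that the ±8 cm⁻¹
quantification windows contain spectrally resolved components and
closed-form checks hold to 1e-6. Real amide-I decomposition requires
second-derivative or curve-fitting deconvolution, which is out of scope.
The phantom also omits transflection optical artifacts (standing-wave
modulation), Mie/resonant-Mie scattering, detector nonlinearity and
spatially correlated noise, and its stripes are not the curved laminae of
real hippocampus. Passing recovery tests therefore demonstrates that the
*analysis chain* is correct and calibrated under its stated noise model —
not that the chain is robust to every artifact of real transflection
measurements.

Synthetic seizure logs plant severity tiers: daily intensities are rounded
clipped Gaussians on the 0–5 (clonic) / 0–3 (tonic) scales, durations are
clipped Gaussians forced to zero on seizure-free days, and clonic/tonic
tier memberships are decoupled by a random permutation. The default tiers
(clonic 5/5/6 animals at daily intensity means 4.0/2.0/0.3; tonic 8/8 at
2.2/0.5) separate cumulative features by far more than 5 pooled standard
deviations, so the planted partition is recoverable by construction —
the clustering tests verify the implementation, not a hard inference
problem. The 0–5 clonic range is itself a convention: the exact modified
limbic-scale definition is configurable.

## Problem sizes and calibration checks

Validation runs at the study's own scale: cohorts of 16 K vs 10 N
phantoms, 48 × 50 × 776 cubes, 17 parameters × 4 layers = 68 comparisons
per cohort. Direction recovery is measured over 50 seeded cohorts;
false-positive calibration pools 20 null-effect cohorts (the discrete
*U* test at n = 16 vs 10 runs slightly conservative, ~0.04 at α = 0.05);
Mann–Whitney calibration additionally uses 1000 independent two-sample
simulations; the integration and Ward oracles use 100 random band draws
and 500 random point sets. Tier recovery uses 50 seeded log cohorts.

## Known limitations

- Integration limits are conventions, not the original instrument values;
  conclusions about absolute areas depend on them (ratios less so).
- "Several hundred" pixel minima for MU/MO are pinned at 300.
- Whether one erosion step reproduces any particular manual border
  exclusion at 25 μm pixels cannot be established; the radius is
  configurable.
- The package does not parse proprietary OMNIC/SPA files; data enter
  through the documented HDF5/text containers.
- No scattering correction or spectral deconvolution is provided.
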