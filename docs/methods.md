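# Methods

`mnlamina` quantifies nuclear-lamina organisation around micronuclei (MN)
in multi-channel 3D fluorescence stacks, and implements the categorical
statistics used to relate MN chromosome content to membrane stability.
This note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Conventions

Arrays are indexed `(z, y, x)`, 0-based. Physical quantities cross module
boundaries in nanometres or micrometres, never in pixels; `VoxelSpacing`
carries the anisotropy (default 20 nm laterally, 150 nm z-step — the
regime of a super-resolution (STED) acquisition with confocal z-sampling).
Channels are addressed by name. Genomic intervals are BED-convention
0-based half-open; adjacent intervals merge.

## Synthetic image model

Every stage is tested against generated data with known ground truth
(`synthetic_data`). The model is deliberately minimal:

- **Geometry.** The MN lamina is an oblate-spheroid shell, default
  semi-axes (1.5, 1.4, 1.0) µm — a 3 µm MN, flattened along z as adherent
  MN are. The shell carries a *soft* Gaussian cross-section of
  σ = thickness/2 (default thickness 0.12 µm). The soft profile matters:
  a hard distance band aliases against the 150 nm z-grid and renders
  spurious concentric dark rings wherever the curved surface slips
  between two plane centres, which a gap detector rightly reports as
  holes.
- **Meshwork texture.** Filaments are the zero level set of a smoothed
  Gaussian random field (correlation length 0.15 µm), with a peaked
  Gaussian cross-section falling to a floor of 0.5 between filaments.
  Real lamin meshwork geometry is *not* modelled — only its line-like
  statistics, which is what the segmentation consumes. The peaked profile
  puts the intensity crest on the filament midline; a flat-top band would
  put ridge crests on the band edges.
- **Gaps.** A `GapSpec` places a gap at a polar/azimuth position with a
  requested projected area and a residual intensity fraction. The
  footprint is rasterised with an exact pixel count, so realized area
  equals requested area to half a pixel; the shell inside the footprint
  (on the gap's hemisphere) is scaled by the residual.
- **Other channels.** DNA fills the interior; H3K27ac fills the interior
  at 1.0 (intact) or 0.39 (ruptured) times the nucleus level — rupture is
  rendered exactly the way it is scored, photometrically, so end-to-end
  rupture concordance is a plumbing check, not biology. Nuclear-pore and
  centromere foci are Gaussian spots of 0.2 µm FWHM with a minimum
  separation (default 0.4 µm).
- **Optics and noise.** Anisotropic Gaussian PSF, default σ = (25, 120) nm
  (lateral, axial) — the axial value emulates a deconvolved stack;
  Poisson noise at 200 photons per intensity unit; additive Gaussian read
  noise σ = 0.01. No SNR was published for the source data; these
  defaults were chosen once for plausible difficulty.

Every generator is a pure function of `(spec, seed)`.

What passing tests on this generator do **not** show: performance on real
meshwork topology (face-size distribution, filament bundling), depth- or
bleaching-dependent intensity, segmentation of touching MN/nuclei, or
teardrop-shaped objects (excluded manually in the source workflow and out
of scope here).

## Meshwork segmentation (`meshwork`)

Per z-plane, an even second-order Gaussian-derivative line filter of
scale 60 nm is steered over 16 orientations from three basis
convolutions; the per-pixel maximal response (bright-line polarity,
clipped at 0) and its orientation are kept. The derivative kernels are
explicitly zero-sum, so a constant image responds exactly 0. Sixteen
orientations keep the worst-case loss against a dense orientation sweep
below 1% of peak — the response varies as A + B·cos 2(θ−θ₀), so the
worst-case sampling loss is (1 − cos(π/n))·B, which is ~1.7% at n = 12
and 0.96% at n = 16.

Non-maximum suppression keeps a voxel iff its response is ≥ both values
interpolated one pixel away along the in-plane ridge normal, thinning
each ridge to a one-pixel crest. Survivors are thresholded on response:
by default the threshold is the Otsu split of log₁₀ responses — in noisy
images the positive-NMS population is strongly bimodal (noise crests vs
filament crests, one to two decades apart) and the log-domain Otsu tracks
that valley at any overall contrast; a guard disables the cut when the
two classes are not genuinely separated (noise-free images). A fixed
quantile can be requested instead. Responses of retained voxels are kept
as segmentation weights. Borders are handled by reflective padding.

## Gap calling (`gap_analysis`)

The equatorial plane is the z-slice maximising the Brenner focus score
Σ(I(x+2,y)−I(x,y))² + Σ(I(x,y+2)−I(x,y))² (classical 2-pixel offset, both
axes; ties break toward the stack middle, then the lower index). The
segmentation splits into bottom = planes [0, z_eq] (equator inclusive,
avoiding double-counting) and top = the rest; each hemisphere is
projected (binary: any-voxel; intensity: max along z — the max is
invariant to how many planes the shell crosses per pixel, so intensity
ratios are comparable between the steep silhouette and the flat cap,
which a mean projection is not).

Before hole labelling, projected centrelines darker than 0.4× the local
filament intensity (0.4 µm max-filter window) are dropped: the ridge
filter is contrast-normalised and happily traces the residual meshwork
inside a gap, which would split one gap into several holes. Remaining
centrelines are dilated to the filter-scale line width. Hole candidates
are 4-connected components of (not meshwork) ∧ footprint that do not
touch the footprint boundary (meshwork 8-connected, holes 4-connected —
the standard duality). Per candidate:

- `mfi_ratio` = mean projected intensity inside the component ÷ mean over
  a ~0.2 µm meshwork annulus around it (outside all candidates; falls
  back to the global footprint mean when the annulus is empty);
- area, perimeter, eccentricity, solidity are measured on the candidate's
  *photometric footprint* — its pixels below 0.5× the reference — because
  a centreline hole necessarily includes the half-width of the
  surrounding mesh cells. This refinement takes the mean absolute area
  error on generated gaps from ≳40% down to ~10%.

A gap is accepted iff area > 0.12 µm² **and** mfi_ratio < 0.5, both
strict — the published cut-offs, derived from the upper envelope of gaps
observed in nuclei. An MN "has a gap" if at least one candidate survives;
gap density is count per µm² of MN area.

Geometric limit: hemisphere projection foreshortens equatorial gaps to
nothing, so recovery experiments (and `sample_gap_specs`) place gaps on
the polar caps. The original projection-based workflow shares this limit.

## Morphometry (`morphometry`)

MN area is the pixel count of the maximum-projection mask × pixel area.
MN volume is the mean of two estimators over the lamin-positive voxel
cloud: the minimum-volume enclosing ellipsoid (Khachiyan iteration on the
convex-hull vertices, tolerance 10⁻⁶; "spanning all voxels" is read as
enclosure) and the exact convex-hull volume. Surface area is derived by
sphere equivalence, S = π^⅓(6V)^⅔ — the minimal assumption consistent
with "derived from the volume". Both estimators measure the *outer lamin
envelope* including the PSF skirt, so on generated shells v_mn runs
~30% above the mid-surface spheroid volume; comparisons across MN are
unaffected because the bias is common mode.

Foci (nuclear pores, centromeres) are detected by a
Laplacian-of-Gaussian filter at σ = diameter/(2√2) laterally, scaled by
the voxel anisotropy axially, normalised so a matched unit-amplitude
Gaussian focus peaks at ~1 (the threshold is then an amplitude, explicit
per image — no auto-tuning, matching how the original analysis gated
foci). Local maxima above threshold are merged when closer than half the
spot diameter and refined to sub-voxel positions by per-axis quadratic
fits. Spot density is count per µm² of derived surface, optionally
normalised to the matched nucleus density.

## Rim intensity and classification (`intensity_class`)

Lamin B1 at the rim: the object mask minus its erosion by 4 px gives the
rim band (A_I, F_I); dilation until area ≥ 2× gives the expanded
selection (A_O, F_O). Background-corrected intensity F_N is computed in
one of three modes: `annulus` (exact ring background,
F_N = F_I − A_I(F_O−F_I)/(A_O−A_I)), `scaled`
(F_N = F_I − (F_O−F_I)·A_I/A_O, the default — the large-expansion
approximation of the ring estimate and almost certainly the intended
reading of the published formula), and `printed`
(F_N = F_I − (F_O−F_I)·A_O/A_I, the formula exactly as printed, kept for
provenance; it yields negative values for typical inputs and is presumed
a transcription error — flagged, not silently corrected).

Rupture: an MN is ruptured iff its H3K27ac mean is below 0.4× the
nucleus mean (a >60% decrease), strictly; 0.40 exactly is intact. The
call is scale-invariant. FISH positivity requires a focus ≥2× local
background (inclusive) co-localising with a centromere. Chromosome number
is the count of centromere foci inside the MN mask. Cells with more than
three FISH foci for one chromosome are excluded (tetraploid or too noisy
to score); zero foci are included but flagged.

## Statistics (`stats`)

For ≥3 groups a family test gates all pairwise testing: Pearson
chi-squared for categorical k×2 tables (flagged invalid on zero cells or
multiple expected counts <5), one-way ANOVA when every group passes
Shapiro–Wilk, Kruskal–Wallis otherwise. Pairwise tests run only when the
family test rejects at α = 0.05: Barnard for counts, Welch t or
Mann–Whitney (matching the family branch) for continuous data, all
Bonferroni-adjusted.

Barnard's unconditional exact test is implemented directly: the pooled
score statistic T = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)) over all outcome
pairs with the observed row totals; the p-value is the supremum over the
nuisance success probability π of the probability of tables with
|T| ≥ |T_obs|, evaluated as a polynomial in π over a 1001-point grid with
golden-section refinement around the grid optimum (grid error < 10⁻⁶ at
these sample sizes; the score variant is the standard modern choice and
cheap enough to verify by full enumeration). φ is
(n₁₁n₂₂ − n₁₂n₂₁)/√(product of marginals) with rows fixed as predictor,
positive level first — callers orient tables. Spearman's ρ uses mid-rank
ties. Post-hoc chi-square power is P(χ²'(df, λ=N·w²) > χ²₁₋α(df)); the
conversion behind the original power report (0.342 from d = 0.5215,
n = 115) is not recoverable from any standard definition — with w = 0.52
and N = 115 the standard formula gives power ≈ 1 — so only the standard
definition is provided.

## LAD genomics (`lad_genomics`)

LAD percentage per chromosome = 100 × |LADs ∖ blacklist| / (chromosome
length − |blacklist|): blacklisted base pairs leave both the numerator
and the denominator, because masked regions can evidence neither state.
Interval sets are sorted, merged (adjacent intervals included) and
subtracted with exact half-open arithmetic, verified against a
base-pair-resolution boolean-array oracle.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` simulates a population (per-class intact probabilities,
binomially sampled), measures every MN (segment → equator → gaps →
morphometry → rupture → foci), writes `measurements.csv` (fixed column
order, 6 significant digits), `gaps.csv`, `stats.json` (family test +
gated pairwise Barnard on the per-class intact/ruptured counts) and a
`manifest.json` with the config hash and seed. One global seed fans out
through the population generator; a re-run with the same configuration is
byte-identical, which is how idempotence is provided (no artifact cache —
determinism makes one redundant at these run times). The `mnlamina` CLI
exposes `simulate`, `segment`, `gaps`, `measure`, `intensity`, `stats`,
`lad` and `run` as thin wrappers.

## Problem sizes

Default test and acceptance runs use MN of (1.5, 1.4, 1.0) µm (~19×171×181
voxels), 50-MN recovery sweeps, 10⁴ null simulations for the exact test's
realized size, and exhaustive Barnard enumeration for row totals ≤ 7 —
sizes chosen so the full suite characterises the estimators well while
remaining quick to re-run on a laptop.

## Known limitations

- Orientation estimation is in-plane only; the 3D structure enters
  through hemisphere splitting, not through out-of-plane steering.
- Gap calling is blind near the equator (projection foreshortening).
- Volume estimates carry the outer-envelope bias described above.
- The intact/ruptured dichotomy is a strict binary at ratio 0.4; the
  intermediate range (0.4–1.0) is reported as intact, as operationalised
  in the source analysis.
- The generator's meshwork is a statistical texture, not a mechanical
  model of the lamina.
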