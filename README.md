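# mnlamina

Quantification of nuclear-lamina organisation around micronuclei (MN),
and the statistics that relate MN chromosome content to membrane
stability.

Micronuclei — small nucleus-like compartments that form around
missegregated chromosomes — rupture when their nuclear envelope fails,
exposing chromatin to the cytoplasm. Whether an MN ruptures tracks with
the organisation of its lamin meshwork: ruptured-prone MN show holes
("gaps") in the lamin A network, reduced lamin B1 at the rim, and fewer
nuclear pores. `mnlamina` implements that image-quantification machinery
for multi-channel 3D fluorescence stacks, plus the categorical statistics
used to analyse the resulting per-MN calls. It is written for
microscopists and computational biologists who want the full pipeline —
segmentation → gap calling → morphometry → classification → statistics —
as reusable, tested library code with a synthetic ground-truth generator
for validation.

## What it computes

**Lamin meshwork segmentation.** Per z-plane, steerable even
second-order Gaussian-derivative line filters (16 orientations, scale
60 nm) with non-maximum suppression along the ridge normal yield
one-pixel filament centrelines, thresholded on response and carried with
their response weights.

**Lamina gap calling.** The stack is split at the equatorial plane found
by Brenner's focus measure, Σ(I(x+2,y)−I(x,y))² + Σ(I(x,y+2)−I(x,y))²;
each hemisphere is 2D-projected and holes in the meshwork are measured
(area, perimeter, eccentricity, solidity, intensity ratio). A hole is a
true gap iff its area exceeds **0.12 µm²** and its interior lamin
intensity is below **0.5×** the surrounding meshwork — cut-offs taken
from the upper envelope of gaps seen in nuclei.

**Morphometry.** MN area from projected masks; volume as the average of
the minimum-volume enclosing ellipsoid and the convex hull of the
lamin-positive voxels; surface area by sphere equivalence
S = π^⅓(6V)^⅔; nuclear-pore (Nup133) foci by matched
Laplacian-of-Gaussian detection at 0.2 µm spot diameter, reported as
foci/µm² normalised to the nucleus.

**Classification.** An MN is *ruptured* iff its H3K27ac mean falls below
0.4× the nucleus mean (a >60% decrease). Lamin B1 rim intensity uses a
4-pixel rim band and a ≥2× expanded background selection with
F_N = F_I − (F_O − F_I)·A_I/A_O. FISH positivity requires a focus ≥2×
local background overlapping a centromere; chromosome number is the
centromere-focus count.

**Statistics.** Family tests (chi-squared / ANOVA / Kruskal–Wallis) gate
Bonferroni-adjusted pairwise comparisons; 2×2 tables use Barnard's
unconditional exact test (score statistic, nuisance maximisation)
implemented from first principles, with the φ coefficient
(n₁₁n₂₂−n₁₂n₂₁)/√(marginal product) for binary association, Spearman's ρ,
and noncentral-χ² post-hoc power.

**LAD genomics.** Per-chromosome lamina-associated-domain percentage from
BED intervals, with blacklist regions subtracted from both LAD coverage
and chromosome length.

**Synthetic data.** A generator renders STED-like anisotropic stacks
(20 nm xy, 0.15 µm z) of oblate-spheroid lamin shells with meshwork
texture, gaps of exactly known projected area, DNA/H3K27ac/foci channels,
Gaussian PSF and Poisson+Gaussian noise — every stage of the pipeline is
validated against this ground truth.

## Worked example

```python
from mnlamina import (AnalysisConfig, GapSpec, SyntheticMNSpec,
                      generate_mn_stack, measure_mn)

spec = SyntheticMNSpec(gaps=(
    GapSpec(theta=0.35, phi=0.8, area_um2=0.25, residual_fraction=0.0),
    GapSpec(theta=2.75, phi=4.0, area_um2=0.40, residual_fraction=0.1),
))
stack, truth = generate_mn_stack(spec, seed=42)
row, gap_records = measure_mn(stack, AnalysisConfig())
```

which prints, when the fields are formatted:

```
rupture call : intact
MN area      : 5.96 um^2
MN volume    : 11.53 um^3  (true mid-surface spheroid: 8.80)
surface area : 24.68 um^2
gap count    : 2  (inserted: 2)
  top    gap: area 0.224 um^2 (inserted 0.25), intensity ratio 0.09
  bottom gap: area 0.363 um^2 (inserted 0.40), intensity ratio 0.15
```

Both inserted gaps are recovered with areas within ~10% and interior
intensity ratios far below the 0.5 cut-off; the volume reads high
relative to the mid-surface spheroid because it measures the outer lamin
envelope (see `docs/methods.md`). The same flow is available from the
shell:

```bash
mnlamina simulate --spec spec.yaml --seed 4 --out mn.ome.tif
mnlamina gaps mn.ome.tif --out gaps.csv
mnlamina run --seed 2 --n-mn 10 --out results/
```

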