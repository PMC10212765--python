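# Methods

## Scope and design

The package implements the single-cell IMC analysis chain as a sequence
of small, separately testable stages exchanging two objects: a
`MultiplexImage` (channel × height × width raster plus a panel of marker
names) and a `CellTable` (one row per cell: centroid, area, mean
intensity per marker, later positivity flags and a lineage label).
Coordinates are 0-based pixel indices with (x, y) = (column, row);
centroids are arithmetic means of member-pixel coordinates. Every
reader/writer pair is an inverse on its own output, and every stage is
deterministic given its seed.

## Synthetic data generator

Because matched patient images of this kind are generally not publicly
deposited, the generator is a first-class module: it draws fields that
emulate IMC acquisition — by default 1000×1000 px at 1 µm/px (~1 mm²),
~1000 cells, a shared nuclear ("DNA") channel and 12 marker channels —
with complete ground truth (instance mask, lineage, per-marker positivity,
centroids).

- **Nuclei** are disks with truncated-normal radii (mean 4 µm, sd 0.8,
  minimum 2 px), chosen because the Laplacian-of-Gaussian response of a
  disk has a closed-form optimal scale (σ* = r/√2), making seed detection
  verifiable analytically. Contested pixels between nearby disks go to
  the nearest center, so instances never overlap.
- **Marker signal**: cell regions are nucleus disks dilated by 2 px
  (whole-cell signal; the compartment is not modeled further). Pixels in
  a positive cell's region are drawn from the marker's foreground
  Gaussian, all others from its background Gaussian (defaults bg
  N(1, 0.3²), fg N(20, 2²)); positivity per (cell, marker) is Bernoulli
  with the lineage's profile probability (0.97 for defining markers, 0.02
  off-target). A Gaussian PSF (default σ = 1 px) and noise (default
  Poisson, emulating count-like IMC acquisition; Gaussian and none
  available) are applied after composition.
- **Lineage abundances** use largest-remainder apportionment rather than
  multinomial draws, so ground-truth cohort fractions equal the
  configured proportions exactly whenever n·p is integral — this is what
  lets an injected +0.10 abundance shift be exactly +0.10 in the truth
  tables. The default panel covers nine lineages (cancer 0.40,
  macrophage 0.15, monocyte/cytotoxic T/helper T 0.08 each, endothelial
  0.06, B 0.06, neutrophil 0.05, Treg 0.04) with PD-1 and Ox40L as
  activation markers.
- **Placement**: complete spatial randomness with an optional hard core
  (default minimum center separation 10 px, preventing merged nuclei); a
  Thomas cluster process (uniform parents, Gaussian offspring) for
  aggregated tissue; and `paired_attraction`, where each cell of an
  attracted type is, with probability `strength`, displaced from a random
  partner cell by an isotropic Gaussian kernel (default sd 8 px) —
  a tunable, monotone interaction signal for the spatial test.
- **Cohorts**: matched pairs share a base configuration; recurrent
  members get shifted lineage proportions (explicitly shifted lineages
  receive exactly p + shift; the remainder is redistributed among the
  others proportionally), foreground means scaled by 2^(log₂FC) for
  selected (lineage, marker) targets, and optionally different placement
  (e.g. attraction only at relapse).

What the generator does **not** emulate: isotope spillover/crosstalk,
autofluorescence, acquisition striping, irregular nucleus shapes, 3-D
effects, intensity gradients across tissue, or cell-density heterogeneity
beyond the point-process choices above. Passing tests therefore establish
that the pipeline's inference is correct when its model assumptions hold,
not that segmentation or gating accuracy transfers to arbitrary real
tissue.

## Segmentation

1. Intensities are rescaled to [0, 1] by the 99.9th percentile (IMC
   dynamic range varies widely between markers and acquisitions).
2. **Seeds**: scale-normalized negated LoG, σ from 2 to 8 px in steps of
   0.5; 3-D local maxima at ≥ 0.1 of the global maximum response;
   non-maximum suppression at 5 px (stronger response wins).
3. **Foreground**: one global Chan–Vese evolution (length penalty
   µ = 0.1, λ_in = λ_out = 1, 200 iterations) initialized from disks of
   radius σ√2 at the seeds. "Initialize from seed disks" is the reading
   adopted for seeded level sets; it keeps the evolution convergent. A
   foreground that covers the whole image raises an error advising a
   parameter change.
4. **Instances**: marker-controlled watershed on the Sobel gradient
   magnitude with the seeds as markers; components under 9 px are
   removed; labels are compacted to {1..K}.
5. **Cells**: nuclei expanded by 3 px via the nearest-nucleus rule
   (`expand_labels`); ties between equidistant nuclei resolve
   deterministically through the distance transform. Nucleus pixels are
   always retained.

All defaults target the 1 µm/px regime and are overridable; none are
claimed to be the values used by any particular published acquisition.

## Marker model and gating

Per marker, per-cell mean intensities (pooled across the cohort for
stability) are fitted with a two-component univariate Gaussian mixture by
EM: k-means initialization, 5 restarts, tolerance 1e-6, at most 500
iterations, seeded. Components are ordered µ_bg < µ_fg. The positivity
threshold is the smallest point in (µ_bg, µ_fg) where the posterior
probability of the foreground component reaches ½ — unique for
well-separated fits and robust to unequal weights, unlike the density
intersection. Fewer than 20 finite values or zero variance raises a
degenerate-input error; EM non-convergence returns the last iterate with
a warning and a `converged=False` flag. The default transform is identity
(appropriate for the synthetic benchmark); `arcsinh` with cofactor 5 is
available for real IMC intensities. Mixtures are fitted on per-cell means
rather than pixels; pixel pools remain accessible through the image
object if a pixel-level fit is preferred.

## Phenotyping

Gating rules are (lineage, required-positive set, required-negative set,
priority) tuples evaluated in ascending priority; the first full match
assigns the lineage and unmatched cells are "unassigned", so assignment
is total and conserves counts. Multi-marker rules precede the
single-marker rules they refine (Treg before helper T, monocyte before
macrophage); permuting priorities of rules with disjoint markers provably
cannot change assignments, and this is tested. Only Treg (CD3⁺CD4⁺FOXP3⁺)
and monocyte (CD14⁺CD68⁻) ship beyond the basic table; further subsets
(MDM, microglia, DC, NK) are left to user-supplied YAML rules rather than
invented defaults.

## Spatial interaction/avoidance test

The neighbor graph connects centroids within `radius_um` (default 15 µm,
conventional at ~1 µm/px). The directional statistic for an ordered pair
(A, B) is the mean count of B neighbors per A cell. The null fixes the
graph and permutes lineage labels over nodes (default 1000 permutations),
which conditions on both the geometry and the lineage multiset. Empirical
one-sided p-values use +1 smoothing, p = (1 + #{null ≥ obs})/(1 + n_perm)
for interaction and with ≤ for avoidance, so p ∈ (0, 1]; z-scores are
(obs − null mean)/null sd with z = 0 when the null sd is 0. Pairs in
which either type has fewer than `min_cells` (default 10) members are
reported with valid=False, p = 1, z = 0. Benjamini–Hochberg correction is
applied within an image across ordered pairs, separately for the
interaction and avoidance families; invalid pairs keep q = 1. Note that
z_(A,B) = z_(B,A) by construction (the normalization cancels the n_a
factor), while the observed statistics differ.

The cohort summary reports, per ordered pair, the mean z per condition,
the paired mean difference of z, and counts of significant images per
condition — descriptive only, as four pairs cannot support per-pair
inference. The same honesty rule applies to the abundance statistics: an
optional Wilcoxon signed-rank flag refuses cohorts under six pairs.

## Cohort statistics

Abundance differences are means over pairs of (recurrent − primary)
fraction, with absent lineages contributing 0 — a fraction difference,
deliberately labeled as such. Fold changes are per-pair
log₂(recurrent mean / primary mean) on raw intensities, averaged over
pairs that have at least `min_cells` cells of the lineage on both sides
and a positive denominator; a result with no surviving pairs is flagged
undefined rather than imputed. Spearman matrices use tie-averaged ranks
(and are cross-checked against Pearson-on-ranks in tests); lineage pairs
with zero variance get NaN.

## Pipeline determinism

Stage seeds derive from SHA-256 of `(global seed, stage name[, sample])`,
truncated below 2³¹, so stages are independently reproducible without
seed bookkeeping. All artifacts (TIFF, CSV with fixed column order and
`%.17g` floats, JSON manifest with sorted keys) are byte-stable, and the
manifest records SHA-256 hashes per stage, enabling both the determinism
check and resume-from-manifest on rerun.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own benchmark sizes: GMM recovery uses 20 fits of
1000 draws; segmentation accuracy a noiseless 200-nucleus 512×512 field
(same density regime as the 1000×1000 default); type-I calibration 50
(tests) / 30 (script) point fields of 300 cells with 3 balanced labels
and 1000 permutations; power 20/10 seeds of 500 cells with attraction
strength 0.9; end-to-end recovery one 4-pair cohort of 1000-cell
1000×1000 fields (plus, in tests, a 20-seed sign check at 1 pair × 400
cells); determinism a full double run at 2 pairs × 120 cells. Calibration
and power operate on generated point patterns directly, since raster
rendering is irrelevant to a test that fixes the graph and permutes
labels.

## Known limitations

- Chan–Vese assumes piecewise-constant intensity; very dim or textured
  nuclei violate it and fall back on the watershed split quality.
- The two-Gaussian model is per marker and global; spatially varying
  background or more than two staining populations are not modeled.
- The attraction placement induces first-order density changes as well as
  pairwise association; the permutation test detects the combination,
  which is what its null (random labels on fixed geometry) measures.
- `expand_cells` resolves equidistant ties deterministically but not by
  the lower label id specifically.
- With ~80 ordered pairs per image and 1000 permutations, the smallest
  achievable BH-adjusted q for a single standout pair is ≈ 0.04; studies
  needing finer FDR resolution should raise `n_perm`.
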