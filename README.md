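# imcspatial

Single-cell spatial analysis of multiplexed imaging mass cytometry (IMC)
tissue images: nucleus/cell segmentation, two-Gaussian marker gating,
rule-based phenotyping, paired primary/recurrent cohort statistics, and
permutation-based neighborhood interaction/avoidance testing — together
with a synthetic-image generator that provides full ground truth, so every
stage of the pipeline is testable end to end without any external data.

It is written for researchers analyzing multiplexed tissue imaging of
tumor microenvironments (e.g. matched treatment-naive and recurrent
glioblastoma pairs), where each ~1 mm² field is acquired at ~1 µm/pixel
with one channel per metal-conjugated antibody.

## Methods at a glance

- **Segmentation.** Nucleus candidates are maxima of the scale-normalized
  Laplacian-of-Gaussian response over scales σ (for a disk of radius r the
  optimum is σ = r/√2); a Chan–Vese level set initialized from seed disks
  recovers the nuclear foreground; a seeded watershed on the gradient
  magnitude splits touching nuclei; cells are nuclei expanded a few pixels
  without crossing neighbors.
- **Marker gating.** Per marker, cell mean intensities are modeled as a
  mixture of two Gaussians — background and foreground staining:
  x ~ w_bg·N(µ_bg, σ_bg²) + w_fg·N(µ_fg, σ_fg²), fitted by EM. A cell is
  positive when its (optionally arcsinh-transformed) intensity exceeds
  the point between the means where P(foreground | x) reaches ½.
- **Phenotyping.** First-match gating hierarchy: Treg CD3⁺CD4⁺FOXP3⁺,
  cytotoxic T CD3⁺CD8⁺, helper T CD3⁺CD4⁺, monocyte CD14⁺CD68⁻,
  macrophage CD68⁺, neutrophil MPO⁺, endothelial CD31⁺, B cell CD20⁺,
  cancer PanCK⁺, else unassigned.
- **Cohort statistics.** Per lineage, the mean over pairs of
  (recurrent − primary) abundance fraction; per (lineage, marker), the
  mean over pairs of log₂(mean intensity recurrent / primary); per
  condition, the Spearman co-infiltration matrix over lineage abundances.
- **Spatial testing.** For each ordered type pair (A, B), the statistic
  is the mean number of B neighbors per A cell within a radius (default
  15 µm). The null permutes lineage labels over the fixed neighbor graph;
  one-sided empirical p-values with +1 smoothing are reported for
  interaction and avoidance, BH-corrected across pairs within an image.

## Worked example

The numbered drivers under `analysis/` run the whole story on a synthetic
4-pair cohort (300 cells per 512×512 field) with three injected effects:
a +0.10 cytotoxic-T abundance shift, a +1 log₂ PD-1 intensity shift on
Tregs, and monocyte–cytotoxic-T attraction present only in recurrent
tissue:

```
python analysis/01_simulate_cohort.py
python analysis/02_segment_quantify.py
python analysis/03_gate_phenotype.py
python analysis/04_abundance_foldchange.py
python analysis/05_spatial_interactions.py
```

Representative output (driver 04 and 05):

```
paired abundance differences (recurrent - primary):
         lineage  abundance_diff  n_pairs
cytotoxic T cell        0.095764        4     <- injected +0.10
...
marker log2 fold changes:
         lineage marker   log2fc  n_pairs_used  defined
            Treg   PD-1 0.950165             4     True   <- injected +1.0

ordered pairs with the largest paired z difference (recurrent - primary):
  type_a           type_b  mean_z_primary  mean_z_recurrent  paired_z_diff ...
monocyte cytotoxic T cell       -0.186518         12.886007      13.072526
```

The pipeline recovers the abundance shift to within 0.005, the fold
change to within 0.05, and flags the injected spatial interaction in 4/4
recurrent images and 0/4 primary ones. Intermediate images live under
`scratch/`, tables under `results/`.

The same pipeline runs on real data through the CLI
(`imcspatial segment|quantify|gate|phenotype|spatial|cohort|run`) given
TIFF channel stacks and a panel CSV.

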