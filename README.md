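# peakshift

Differential transcription-factor occupancy analysis for ChIP-seq peak sets.

Signal-dependent transcription factors such as the STATs can occupy entirely
different genomic sites before and after a stimulus: the unphosphorylated
factor may sit at architectural (CTCF-proximal) sites in resting cells, while
the activated, phosphorylated form is recruited to consensus (GAS) motifs
after cytokine treatment. `peakshift` implements the comparative analyses
needed to characterise such a redistribution from peak calls alone:

* **Occupancy classification** — peaks from N conditions are standardized to
  a fixed width around their summits, filtered for repetitive sequence, and
  merged into a non-redundant region universe; each region gets a
  presence/absence pattern across conditions (`A_only`, `B_only`, `shared`,
  or the membership list for N > 2), plus a binned per-condition coverage
  matrix for heatmap display.
* **Colocalization** — peak-based Venn overlap counts, conditional loss
  fractions (how many colocalized peaks disappear in a later condition), and
  a TF×TF Pearson correlation matrix over binary union-region occupancy with
  Ward-linkage leaf ordering, the standard representation for TF co-binding
  heatmaps.
* **Motif position statistics** — log-odds PWM scanning on both strands;
  motif prevalence; central motif enrichment (CentriMo-style: do best sites
  cluster at the peak center?) and primary–secondary motif spacing
  (SpaMo-style: is a partner motif found at a preferred gap and
  orientation?), both tested with exact upper-tail binomial nulls under
  uniform site placement, Bonferroni-corrected.
* **Tiered gene mapping** — promoter overlap, then gene-body overlap, then
  the nearest gene within 50 kb on each side (both reported when both flanks
  have one).
* **Expression integration** — RPKM, strict FDR/fold-change selection of
  differentially expressed genes (FDR < 0.001, |FC| > 1.5), and the fraction
  of DE genes annotated to peaks (direct targets).
* **Synthetic data** — a seeded generator that plants occupancy clusters,
  motif pairs at controlled spacing (e.g. CTCF + ETS separated by exactly
  7 bp), central GAS sites, proximal genes and correlated DE tables, with a
  machine-readable truth object, so every stage of the pipeline can be
  validated against known ground truth.

The centrality statistic: with best-site centers `c_i` in `n` equal-length
sequences and a central window of halfwidth `h` containing a fraction `π_h`
of all possible site centers, the number of sequences with `|c_i − mid| ≤ h`
is Binomial(n, π_h) under uniform placement; the smallest upper-tail p over
a halfwidth grid is reported after Bonferroni multiplication. The spacing
statistic bins the best secondary site per anchored sequence into
(gap, quadrant) cells, gap ∈ [0, 150], quadrant ∈ {same/opposite strand} ×
{left/right of the primary site}, and tests the fullest cell against the
uniform cell probability `1/(4·151)`.

## Worked example

Simulate a two-condition study (40 condition-A-specific regions carrying a
CTCF consensus with an ETS site 7 bp downstream, 40 condition-B-specific
regions with a central GAS site, 20 shared regions) and run the full
pipeline:

```bash
peakshift simulate --outdir demo --seed 7 \
    --n-a-only 40 --n-b-only 40 --n-shared 20 --mask-fraction 0
peakshift run-all demo/config.yaml
```

Key lines of the printed summary:

```
n_regions.A_only        40
n_regions.B_only        40
n_regions.shared        20
venn.fraction_A_in_B    0.3333
centrality.motif        CTCF
centrality.p            1.772e-50
spacing.best_gap        7
spacing.best_quadrant   same-strand/right
spacing.p               3.464e-109
gene_mapping.promoter   40
de.n_up                 40
de.direct_up            40
de.direct_up_percent    100
```

The classifier recovers all 100 planted occupancy patterns; the planted
7-bp same-strand CTCF–ETS spacing is recovered with overwhelming
significance; the CTCF motif is centrally enriched in A-specific regions;
each A-specific region maps to its planted target gene through the
promoter tier; and all 40 planted DE targets are recovered as direct
targets (100%). On real data the same summary reports, for example, the
fraction of condition-specific peaks colocalizing with CTCF and the
percentage of up/downregulated genes that are direct binding targets.

Every subcommand (`standardize`, `classify`, `venn`, `coloc-matrix`,
`features`, `centrimo-lite`, `spacing`, `map-genes`, `integrate`) is also
available standalone; the same functionality is importable from
`peakshift` as a library.

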