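# Reproducing the full-scale published analysis

The desk-scale validation in this repository runs on synthetic data with
planted ground truth. The original genome-scale figures — occupancy
cluster sizes of 4,109 (unstimulated-specific), 771 (stimulated-specific)
and 198 (shared) STAT5 regions; 64% of unstimulated-specific peaks
colocalizing with CTCF; 97% of those CTCF-colocalized peaks lost after
thrombopoietin stimulation; and 75% of STAT5+CTCF sites also bound by
ERG — derive from deposited deep-sequencing data and can be re-derived
with this package as follows. Exact equality with the published counts is
not guaranteed: the region universe depends on the upstream peak-caller
version and its parameters, which are outside this package's scope.

## Inputs

1. STAT5 ChIP-seq of HPC7 cells, unstimulated (T = 0) and TPO-stimulated
   (T = 30 min): GEO accession **GSE70697** (raw reads and processed
   files, including the STAT5-knockdown RNA-seq used for the DE table).
2. CTCF ChIP-seq in HPC7 cells and the ten-factor hematopoietic TF
   compendium (FLI1, ERG, SCL/TAL1, GATA2, RUNX1, …) from their published
   GEO accessions.
3. Mouse genome FASTA (UCSC mm9 soft-masked, the build used for the
   original coordinates) and the UCSC gene table for the same build.

## Steps

1. Call peaks per condition against the IgG control with MACS
   (summit-reporting narrowPeak output). Peak calling is deliberately out
   of scope here; any MACS 1.4/2.x workflow that emits summits works.
2. `peakshift standardize` each peak file (400 bp summit-centered), then
   repeat-filter against the soft-masked genome (>40% repeat content
   excluded) — both are applied automatically by `peakshift run-all`.
3. `peakshift classify` on the T0 and T30 standardized sets: the three
   cluster counts correspond to `A_only`, `B_only` and `shared` regions.
4. `peakshift venn` of the T0-specific set against CTCF peaks gives the
   colocalization fraction; `peakshift.colocalization.subset_overlapping`
   plus `conditional_loss_fraction` against the T30 set gives the loss
   fraction; a second `venn` of the STAT5∩CTCF subset against ERG peaks
   gives the ERG co-occupancy fraction.
5. `peakshift coloc-matrix` across all eleven factors reproduces the
   pairwise-overlap correlation heatmap input (Ward leaf order included).
6. `peakshift centrimo-lite` / `peakshift spacing` with CTCF/ETS/GAS PWMs
   (e.g. JASPAR MA0139, MA0098, MA0519) over the T0-specific regions test
   central CTCF enrichment and the CTCF–ETS spacing preference.
7. `peakshift map-genes` on the T0-specific regions with the UCSC gene
   table, then `peakshift integrate` with the knockdown DE table
   (FDR < 0.001, FC > 1.5) reproduces the direct-target percentages.

A config file driving steps 2–7 in one `peakshift run-all` invocation is
the recommended route; every output embeds the parameters used.
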