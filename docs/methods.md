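# Methods

This note documents the models and procedures implemented in `peakshift`,
their assumptions, parameter defaults, and the numerical and design
choices made where the methodology was genuinely open.

## Coordinate model and peak standardization

All internal coordinates are 0-based half-open (BED convention); strand-aware
1-based conversion happens only in human-readable output. Peaks are
standardized to a fixed width (default **400 bp**) centered on the peak
summit — the single-bp position of maximal read enrichment reported by the
peak caller (narrowPeak column 10). When the input is plain BED6, or the
summit offset is −1, the floor midpoint substitutes for the summit.
Fixed-width peaks make overlap statistics and motif position statistics
comparable across datasets whose peak callers produce different peak
geometries. Standardized intervals are clamped at chromosome bounds when
chromosome sizes are known.

Peaks with more than **40%** repetitive sequence over the standardized
interval are excluded (a peak at exactly 40% is kept; the threshold is
strict). Repetitive bases come from soft-masked lowercase in the genome
FASTA by default; an explicit repeat-interval BED takes precedence when
given. ChIP-seq enrichment inside high-copy repeats is dominated by
mapping artifacts, which is why repeat-heavy peaks are removed before any
motif analysis.

## Occupancy classification

Peaks from all conditions are pooled and merged into non-redundant regions
(any base-pair overlap merges; book-ended intervals stay separate). Each
region's occupancy bit for condition *c* is set iff at least one peak of
*c* overlaps the region by at least `min_overlap_bp` (default **1 bp**; the
choice of threshold is exposed because reasonable analyses vary between
1 bp and half the peak width). The union-merge-then-membership design was
chosen over reciprocal pairwise matching because it expresses "present
only in condition X" and "unchanged" with a single rule and generalizes
to any number of conditions. The region summit and score are inherited
from the highest-scoring contributing peak.

Cluster labels are a pure function of the bit pattern: one bit set →
`<cond>_only`, all bits set → `shared`, anything else → the "+"-joined
member list.

The heatmap matrix bins per-condition coverage (bedGraph input) into
**50 bp** bins over a **5 kb** window centered on each region summit,
scaled per-million (values × 1e6 / total track signal). Rows are grouped
by cluster label and ordered by descending first-condition signal within
each group; the within-cluster ordering is a display choice with no
downstream effect.

## Colocalization

Venn overlap counts are peak-based, not merged-region-based, and therefore
direction-dependent: `both_a` counts peaks of A overlapping ≥ 1 peak of B,
`both_b` the converse. Both directions are always reported. The
conditional loss fraction takes a colocalized subset (e.g. peaks of A that
overlap factor X) and reports the fraction with no overlap in a later
condition's peak set.

For the TF×TF correlation matrix, every peak set is vectorized as binary
occupancy over the union-region universe of all sets, and Pearson's r is
computed between these 0/1 vectors. Binary occupancy was chosen because it
is the standard vectorization for TF co-binding heatmaps and is exactly
recomputable by brute force in tests. Hierarchical clustering uses Ward
linkage on distance 1 − r, the conventional distance for correlation
heatmaps. A set occupying all or none of the union regions has zero
variance; its correlations are undefined and reported as NaN with a
warning, and it is placed after the clustered leaves.

Feature distribution assigns each peak by its **summit** (not any-overlap)
to the first matching category in the precedence promoter > gene body >
intergenic. The promoter window is strand-aware
[TSS − 2000, TSS + 500). The −2000/+500 default is configurable and echoed
into output metadata, because curated promoter databases differ and are
generally not reconstructible; any consistent window supports the
promoter-enrichment ratio between conditions, which is a ratio of promoter
fractions computed with identical gene models.

## Motif statistics

PWMs are regularized at load time with pseudocount **0.1 × background**
and row-renormalized, so log-odds are finite. Scores are natural-log odds
Σ ln(p_i(base)/bg(base)); both strands are scanned, reverse-strand hits are
reported at the forward-strand coordinate of the site's leftmost base, and
N bases contribute 0 (background odds). Ties in best-site selection break
toward the smaller offset, then the + strand, making every downstream
statistic deterministic.

Both position statistics anchor on the **best site per sequence with no
score threshold**, as CentriMo and SpaMo do; this avoids an arbitrary hit
cutoff, at the cost that sequences without a real site contribute a
quasi-uniform background anchor, which only dilutes (never inflates) a
true positional signal.

**Central enrichment.** For equal-length sequences, the best-site center
c = offset + L/2 is compared to the sequence midpoint. For each halfwidth
h in a grid (default 5, 10, 20, 50, 100, 150 bp, truncated below half the
sequence length), the count of sequences with |c − mid| ≤ h is tested
against Binomial(n, π_h), π_h being the fraction of possible site centers
inside the window. The minimal upper-tail p over the grid is multiplied by
the number of halfwidths tested (Bonferroni) and capped at 1. Under
uniform site placement this null is exact, which makes the test
calibratable by construction: planting sites at uniform random offsets
reproduces the null exactly, and the acceptance suite verifies a ≤ 5%
rejection rate at α = 0.05 over 1000 replicates (discreteness plus
Bonferroni make the test conservative, empirically ~2–3%).

**Spacing.** The anchor is the best primary site; sequences whose anchor
lies within `max_gap + L₂` of either edge cannot host every candidate gap
and are dropped (counted). The best secondary site is searched among all
placements with gap 0…`max_gap` (default **150 bp**) on either side; the
gap is the distance between the two sites' nearest edges. Each anchored
sequence contributes one (gap, quadrant) observation, the quadrant being
side × relative strand **oriented by the primary site's strand** (a
downstream partner of a − strand anchor is "right"). The fullest of the
4·(max_gap+1) cells is tested against Binomial(n, 1/(4·(max_gap+1))) and
Bonferroni-multiplied by the cell count. This uniform-cell binomial is a
simpler null than SpaMo's exact enumeration; it recovers the same best gap
on planted data but its p-values are not numerically comparable to
SpaMo's.

Prevalence uses the only thresholded criterion in the module: the fraction
of sequences whose best-site score reaches `score_fraction` (default
**0.8**) of the maximum attainable PWM score.

Sequence inputs follow two conventions: 100 bp summit windows for
discovery-style analyses, 400 bp standardized peak regions for centrality
and spacing; both are configuration options.

## Gene mapping

Tiers are evaluated in order; the first non-empty tier wins:

1. **promoter** — genes whose promoter window overlaps the peak;
2. **gene_body** — genes whose body overlaps the peak;
3. **flank** — the nearest gene within **50 kb** on each side of the peak;
   genes on both sides give `flank_both` with both genes reported;
4. **unassigned**.

Distances are peak-edge to gene-edge, 0 for overlaps. When more than two
genes tie within a direct-overlap tier, the gene whose TSS is nearest the
peak summit is kept (one or two overlapping genes are all kept).
Equidistant ties within a single flank side keep the lexicographically
smallest gene id so assignments never exceed two genes; the two-sided
flank case inherently reports both. Shrinking the flank window can only
lose assignments (monotonicity, property-tested).

## Expression integration

DE statistics are consumed, not computed — a DESeq-style table of
(gene, log2FC, FDR) is the interface. Selection uses strict
FDR < **0.001** and |log2FC| > log2(**1.5**); a gene exactly at the FDR
cutoff is excluded, and the fold-change threshold is applied symmetrically
in log2 space. RPKM = count / (length/1000) / (library/10⁶). The direct-
target fraction counts DE genes appearing as any gene id in any peak
assignment (duplicates count once) and reports the fraction to 3 decimals
plus the nearest-percent figure.

## Synthetic data generator

The generator emulates a two-condition differential-occupancy study:

* i.i.d. genome at configurable GC (default 0.5), two 500 kb chromosomes,
  with optional soft-masked "repeat" blocks (500 bp blocks, default
  fraction 0.05 in the simulator CLI);
* planted regions ≥ 1 kb apart with known condition membership; A-specific
  regions carry the CTCF consensus with an ETS consensus exactly **7 bp**
  downstream on the same strand, B-specific regions a central GAS
  consensus — the motif plan is configurable per pattern;
* per-condition peak sets with controllable width jitter, summit noise,
  false-positive and false-negative rates (defaults 0 — the noise-free
  recovery conditions — with 5% dropout as the standard perturbed
  condition);
* one target gene per A-specific region whose promoter overlaps the
  region's peak (TSS 1 kb downstream of the region center), so tiered
  mapping links each region to its own gene deterministically, plus
  background genes kept 60 kb clear of every region;
* a DE table in which target genes draw log2FC ~ Normal(1.5, 0.2) and
  FDR ~ U(0, 10⁻⁶), and background genes draw log2FC ~ Normal(0, 0.2) and
  FDR ~ U(0, 1).

Consensus sequences are planted verbatim rather than sampled from the
PWM, so recovery tests are deterministic; a sampling mode exists for
stochastic tests. All generators are pure functions of (parameters, seed),
and a JSON truth sidecar records every planted coordinate.

What the generator does *not* emulate: mappability structure, fragment-
length effects on peak shape, copy-number variation, correlated biological
replicates, motif degeneracy gradients, or realistic gene density and
overlap. Passing recovery tests therefore demonstrates the correctness of
the algorithms under their stated models, not robustness to every artifact
of real sequencing data.

## Problem sizes and numerical choices

The bundled validation runs use 300 planted regions for occupancy
recovery, 50 planted pairs for spacing, 100 sequences × 1000 replicates
for centrality calibration, and ≤ 50 peaks/genes per instance for the
brute-force oracle comparisons — sizes at which the exact oracles are
cheap while all asymptotics of interest are already visible. Binomial
tails come from `scipy.stats.binom.sf`; window probabilities are clipped
to [1e-12, 1−1e-12] before the tail call; p-values of 0 are reported as
−log10 p = 350 in the acceptance summary. Ward linkage and leaf ordering
come from `scipy.cluster.hierarchy` on the condensed, symmetrized 1 − r
matrix clipped at 0.

## Known limitations

* The spacing null treats the best secondary site's (gap, quadrant) as
  uniform; weak sequence-composition effects (e.g. GC skew) can deviate
  from uniformity slightly, which matters only near the significance
  boundary.
* Peak-based Venn counts are not symmetric between sets and will not match
  merged-region counts when peaks of one set chain across several peaks of
  the other.
* Gene mapping reports at most two genes per peak; dense loci with more
  than two genuinely equidistant candidates are truncated by the
  nearest-TSS rule.
* The repeat filter sees only the repeat evidence it is given; an
  unmasked genome with no repeat BED keeps everything.
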