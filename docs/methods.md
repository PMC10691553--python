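# Methods

This note documents the models, conventions, parameter choices and known
limitations behind each analysis stage, and what the synthetic-data
generator does and does not emulate.

## Coordinates and annotation handling

All intervals are 0-based half-open internally; GFF3 I/O converts from the
1-based closed convention at the boundary, BED passes through. Exons are
sorted and merged when they overlap or are bookended. TE classifications are
normalized onto a closed vocabulary (DNA, RollingCircle, LINE, SINE, LTR,
PLE, Other) by their leading token, so `DNA/hAT-Tip100` → DNA and
`RC/Helitron` → RollingCircle; unrecognized strings map to Other with a
logged warning rather than an error, since repeat libraries routinely carry
idiosyncratic labels.

**Defragmentation.** Repeat callers split single insertions into fragments.
`defragment` merges consecutive same-family, same-chromosome fragments whose
gap is at most `max_gap` (default 200 bp, configurable) when strands are
compatible; strand `.` merges with either strand because many TE callers
omit strand. The merge is transitive left-to-right; merged divergence is the
length-weighted mean of the known fragment divergences. The 200 bp default
is a package choice — upstream annotation pipelines defragment before
export without publishing a universal threshold — and is deliberately
conservative. Overlaps between *different* families are handled separately
by `resolve_overlaps`: the longer copy keeps its span and shorter copies are
truncated to the unoccupied remainder (a copy split in the middle keeps all
remaining pieces). This step only matters for per-classification bp
attribution; coverage statistics use interval unions and never double-count
a base either way.

## Compartment partitioning

Each base receives exactly one label with precedence
exon > intron > flank > intergenic. Flanks extend `flank_size` (default
20 kb — wide enough to include proximate promoter and distal enhancer
space) from the gene body and are labeled 5′ or 3′ relative to gene strand.
Where the flanks of two genes collide, each base is assigned to the nearer
gene (distance to the closest gene-body base); exact ties prefer the 5′
flank, then the left gene. Among genes sharing a body boundary the one
whose flank would be 5′ wins, then lexicographic id — arbitrary but
deterministic. The partition is exact: intervals are disjoint, sorted, and
sum to the chromosome length, which the tests enforce against a per-base
brute-force labeler on hundreds of randomized genomes.

Published analyses of this kind do not state whether flank intervals were
clipped at neighboring genes before intersection; the disjoint nearest-gene
partition used here is one defensible reading, and per-compartment
percentages may therefore differ slightly from numbers produced by
overlap-tolerant pipelines.

**Locus windows deliberately differ from the partition**: the per-gene
window (gene body ± flank) does *not* exclude neighboring genes' bp, and a
TE overlapping two windows counts for both loci, matching the per-gene
intersection procedure the enrichment analysis mimics. One defragmented
insertion counts once per window regardless of how many compartments it
spans. Coverage is the union of clipped TE intervals, so nested or
overlapping TE calls cannot inflate it.

**Compactness** is genic (exon + intron) over intergenic (flanks +
intergenic space) bp, reported raw and rounded to two decimals
(round-half-even); zero intergenic bp yields an infinity sentinel.

## Enrichment statistics

Fold-change is the ratio of focal to background means, reported raw and
display-rounded (round-half-even, one decimal by default; published tables
that round the same ratios inconsistently are the reason the raw value is
always kept alongside). Significance uses the two-sided Wilcoxon rank-sum
test with midranks: exact enumeration when the pooled sample is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
correction; the statistic reported is the Mann–Whitney U of the focal
sample (the W of R's `wilcox.test`). Cross-category and cross-species
comparisons use Kruskal–Wallis with tie correction (all-identical data
degenerate to H = 0, p = 1). No multiple-testing correction is applied by
default, matching the raw-p reporting convention of the analyses this
package reimplements; a Benjamini–Hochberg helper is provided.

**Hotspots.** A locus is called when TE coverage exceeds the coverage
threshold AND the insertion count exceeds the count threshold (strict
inequalities; defaults 35 kb and 80). Gene-size Z-scores are computed
within (species, category) with the population SD; fewer than three
category members or zero SD yield a NaN sentinel. The TE-excised variant
subtracts TE bp overlapping the gene body (not the flanks) before
standardizing: a locus with a raw Z > 3 but an excised Z < 3 owes its size
to TE sequence. Z-scores pool within species rather than across species —
the alternative reading is available by concatenating inputs.

**Regression and heritability.** The genome-size / TE-content association
is ordinary least squares with the one-slope F statistic (t²) and R².
Phylogenetic heritability is computed per posterior sample as
r = Vp/(Vp + Vs) (samples with zero total variance are dropped with a
warning); the point estimate is the posterior mean of r and the interval is
the shortest window over the sorted ratios containing 95 % of them. Fitting
the Bayesian phylogenetic mixed model that produces the samples is out of
scope; the function consumes supplied posterior draws.

**CYP functional contrasts.** Two per-species contrasts on CYP genes:
resistance-linked (labels xenobiotic, insecticide, natural) versus
other-function, and insecticide versus natural. Arms with fewer than two
genes skip the contrast with a warning.

## Kimura divergence and repeat landscapes

The Kimura two-parameter distance −½·ln((1−2p−q)·√(1−2q)) is computed from
transition (p) and transversion (q) fractions over ungapped, non-N
alignment columns. Outside its domain (1−2p−q ≤ 0 or 1−2q ≤ 0) the distance
is saturated and an error is raised rather than returning a clamped value.
CpG adjustment follows the standard repeat-divergence convention, since
"CpG adjusted" is named but not specified in the literature this mirrors: a
transition at a consensus CpG dinucleotide counts 1/10 of a substitution,
and two transitions within one CpG site count as a single weighted
transition; transversions are never down-weighted. Landscapes accumulate
each copy's bp into `floor(divergence·100)` bins of width 1 % up to 50 %
(both configurable; the conventional plotting range). Copies lacking a
divergence are skipped; divergences past the last bin clamp into it with a
warning.

## Family clustering (80/80 rule)

Consensus sequences from all species are clustered greedily in
length-descending order: a sequence joins the qualifying representative
(identity ≥ c over ≥ aS of the shorter sequence, defaults 0.8/0.8, both
strands searched) with the highest identity — ties to the longer
representative, then id order — or founds a new cluster. Alignment is exact
local alignment (match +1, mismatch −1, gap open −2, gap extend −1) via
Bio.Align.PairwiseAligner rather than a word-filter heuristic; the scoring
scheme is a package choice, as the heuristic tool commonly used for this
step does not document one. A candidate prescreen skips dynamic programming
for pairs that provably cannot qualify: any alignment meeting the
thresholds implies an infix edit distance of the shorter sequence against
the longer of at most ((1−c)/c + (1−aS))·L_short, so pairs beyond that
bound (checked with edlib on both strands) are rejected exactly, not
heuristically. Known reference families that keep one library name across
species can bypass alignment via `by_name=True`. Borderline pairs may still
cluster differently than banded heuristic tools — unbanded exact alignment
finds alignments such tools can miss.

Sharing is the number of *other* species represented in a cluster (0 =
species-specific); the per-species sharing profile rows sum to 100 % of
that species' families.

## Expression

RPKM = reads·10⁹/(transcript length · library size), with transcript length
taken as the sum of exon lengths (the length convention is not stated in
the source analyses). Germline contrasts compare focal-gene RPKM against
housekeeping genes per tissue (testis, ovary) and pooled, where pooling
averages each gene's RPKM across germline tissues before testing; library
sizes are per-tissue.

## Synthetic data generator

The generator emits complete annotation bundles (chromosome sizes, gene
GFF3 with exon structure, TE GFF3 with family/classification/divergence
attributes, category tables, per-species consensus FASTA, expression TSV,
and a truth table of every planted parameter). Design choices:

- **Genes** are placed without overlap, with Dirichlet-distributed gaps,
  Poisson(+1) exon counts and log-normal exon/intron lengths. Category
  fractions default to 2 % per detoxification family and 2 % housekeeping —
  deliberately higher than real genome-wide fractions so that desk-scale
  genomes (default 3 species × 2 chromosomes × 2 Mb, 150 genes) contain
  enough focal genes to estimate anything.
- **TE insertions** follow a Poisson process (default 250 insertions/Mb)
  with log-normal lengths (mean 536 bp, σ = 1.0 — a heavy right-skewed
  fragment distribution; σ is a package choice). The defaults give a
  genome-wide TE fraction near 13 %, inside the range observed across
  aphid genomes.
- **Enrichment is planted mechanistically**: inside focal-category locus
  windows the insertion rate is multiplied by the count multiplier and
  lengths are scaled by coverage/count, so estimators are validated against
  a generative mechanism rather than labels applied after the fact.
- **Classification mixture** anchors the DNA-transposon share at 45.27 %
  (the dominant-classification share reported for aphids) and fills the
  remaining classes with plausible shares; only the DNA share is an
  anchored literature value.
- **Families** form a global pool with ~10 % shared by all species, ~47 %
  species-specific, and the remainder shared by subsets — the qualitative
  sharing structure reported for aphid TE families. Shared families receive
  per-species consensus variants mutated by 2.5–10 %, keeping pairwise
  identities in the 80–95 % band the clustering stage must resolve.
- **Copy divergences**: families are "recent" (ages 0.01–0.10, 70 % of
  families) or "old" (0.20–0.40); copies jitter ±30 % around the family
  age. Simulated copy *sequences* are substitution-only (no indels) with
  CpG transitions at 10× the background rate — the hypermutability the
  1/10 CpG down-weighting corrects — so the divergence estimator recovers
  planted ages nearly unbiasedly.
- **Expression** draws Poisson read counts at target RPKM means
  (housekeeping 50, focal 5, other 20) for the first species only.

What the generator does **not** emulate: nested/fragmented TE insertions
with excision footprints, indel evolution of TE copies, assembly artifacts,
GC/chromatin heterogeneity in insertion rates, and realistic gene density
(real genomes are far denser, making locus windows overlap heavily).
Passing recovery tests therefore shows the estimators are correct under the
stated generative model, not that biological confounders are handled.

## Calibration and recovery experiment designs

The planted-enrichment recovery experiment (used by the acceptance checks)
places 300 focal and 300 background genes at ~4 Mb spacing with a low TE
density (50 insertions/Mb) and the standard 20 kb flanks. The sparse
spacing and low density are deliberate: the fold-change estimator carries
three small negative biases under mechanistic planting — union saturation
of coverage inside dense windows, boundary-crossing insertions that add
equal absolute bp to both arms, and contamination of background windows
that overlap enriched focal windows — and this design keeps their combined
effect within a few percent (about −10 % at the strongest planted
multiplier, 5×), so planted multipliers of 1.5/2.4/5 are recovered within
±20 % per replicate. Null calibration uses 200 smaller genomes (2 Mb, 60
genes, 5 kb flanks) with no planted enrichment; the mean fold stays within
[0.9, 1.1]. Rank-sum type-I error is measured on 2 000 null draws at
n = 50 per arm. Problem sizes throughout were chosen as the smallest that
give the estimators tight sampling distributions.

## Numerical conventions

Round-half-even everywhere a rounded value is displayed (Python `round`).
Population (not sample) SD in Z-scores. NaN sentinels for undefined
quantities (zero background mean, zero SD, < 3 category members) rather
than exceptions, so tables stay rectangular; genuinely invalid inputs
(empty samples, saturated distances, negative gaps) raise. All randomness
flows through a single `numpy` Generator seeded from the config, and every
writer emits sorted, deterministic output so identical seeds give
byte-identical files.

## Known limitations

- Greedy clustering is order-dependent by design (length-descending, id
  tie-break); it reproduces the conventional tool's semantics, not a
  globally optimal partition.
- The compartment partition resolves flank collisions by nearest gene; any
  published number produced without clipping flanks at neighboring genes
  will differ in dense regions.
- Fold-change of means is sensitive to heavy upper tails; the rank-sum
  p-value is the robust companion, and both are always reported.
- De novo TE discovery, ortholog identification, phylogeny estimation and
  Bayesian mixed-model fitting are out of scope; the package consumes their
  outputs.
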