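# telocus

Comparative analysis of transposable-element (TE) accumulation at gene loci,
built for the question of whether detoxification ("xenobiotic") gene families
— cytochrome P450s (CYP), glutathione S-transferases (GST), esterases,
UDP-glucuronosyltransferases (UGT) and ABC transporters — attract more TE
sequence than the rest of the genome, as repeatedly observed in
insecticide-resistant insects such as aphids.

The package takes standard annotation inputs (gene GFF3, TE GFF3/BED,
chromosome sizes, a gene-category table, consensus FASTA, optional read
counts) and provides:

- **Compartment partitioning** — every base of a chromosome is labeled
  exon / intron / 5′-flank / 3′-flank / intergenic (flanks default to 20 kb,
  the proximate-promoter scale; contested flank bases go to the nearest
  gene), with TE occupancy per compartment and the genome-compactness
  statistic genic:intergenic bp.
- **Locus profiling** — per-gene TE coverage (union bp) and insertion count
  over the locus window (gene body ± flank), overall and per TE
  classification (DNA, rolling circle, LINE, SINE, LTR, PLE).
- **Enrichment statistics** — fold-change of focal gene sets over background
  genes with two-sided Wilcoxon rank-sum tests (exact for small tie-free
  samples), Kruskal–Wallis comparisons across categories and species,
  per-species enrichment tables, and CYP functional contrasts
  (resistance-linked vs other; insecticide vs natural xenobiotics).
- **Hotspot calling** — loci exceeding configurable thresholds (default
  >35 kb TE sequence and >80 insertions), with gene-size Z-scores computed
  before and after excising genic TE bp to separate TE-driven size inflation
  from intrinsically large genes.
- **Repeat landscapes** — CpG-adjusted Kimura two-parameter divergence of
  each TE copy from its family consensus, binned into bp-per-divergence
  histograms (low divergence ≈ recent activity).
- **Family clustering** — greedy 80/80 clustering of consensus libraries
  across species (≥80 % identity over ≥80 % of the shorter sequence, both
  strands, CD-HIT-EST-style greedy assignment with exact local alignment),
  yielding per-species family-sharing profiles.
- **Expression contrast** — RPKM normalization and a germline
  (testis/ovary) comparison of focal genes against housekeeping genes.
- **Synthetic data** — a generator that emits complete multi-species
  annotation bundles with *planted* enrichment, divergence, and family
  sharing, so every estimator is tested against a generative truth.

## Core statistics

For a focal gene set F and background B with per-locus TE metric x
(coverage bp or count), enrichment is the ratio of means

    fold = mean(x_F) / mean(x_B)

tested with the two-sided Wilcoxon rank-sum statistic (midranks, tie and
continuity corrected; the reported W is the Mann–Whitney U of the focal
sample). Gene-size hotspot Z-scores use the population SD within
(species, category); the TE-excised variant standardizes
`gene_length − genic_TE_bp`. TE copy divergence follows the Kimura
two-parameter model

    d = −½ · ln((1 − 2p − q) · √(1 − 2q))

with transitions at consensus CpG dinucleotides down-weighted to 1/10 (two
transitions within one CpG count once). Phylogenetic heritability of a trait
is Vp/(Vp + Vs) over paired posterior samples of the phylogenetic and
species-specific variance components, reported with the shortest 95 %
highest-posterior-density interval.

## Worked example

Simulate a three-species bundle with a 2.4× TE enrichment planted at CYP
loci, then measure it:

```python
from telocus import (SimConfig, simulate_genome, defragment, profile_locus,
                     build_compartment_map, compactness_ratio)
from telocus.enrichment_stats import locus_table, species_enrichment_table

sim = simulate_genome(SimConfig(enrichment={"CYP": (2.4, 2.4)}), seed=42)
sp = sim.species["species0"]
tes = defragment(sp.tes, max_gap=200)
cmaps = [build_compartment_map(sp.genes, c, flank_size=20_000) for c in sp.chrom_specs]
comp = compactness_ratio(cmaps)
print(f"genic:intergenic = {comp.genic_bp}:{comp.intergenic_bp} bp (ratio {comp.ratio_rounded})")
profiles = profile_locus(sp.genes, tes, sp.chrom_specs, flank_size=20_000)
table, _ = species_enrichment_table(
    {"species0": locus_table(sp.genes, profiles, "species0")}, focal_categories=["CYP"],
)
print(table[["species", "metric", "focal_mean", "background_mean",
             "fold_change", "p_value"]].to_string(index=False))
```

prints

```
genic:intergenic = 367607:3632393 bp (ratio 0.1)
 species      metric   focal_mean  background_mean  fold_change  p_value
species0 coverage_bp 13111.000000      4761.911565          2.8 0.005686
species0       count    27.333333        10.571429          2.6 0.003268
```

The three planted CYP loci carry ~2.8× the TE coverage and ~2.6× the
insertion count of the other 147 genes (rank-sum p < 0.01); the estimate is
noisy at three focal genes but recovers the planted 2.4× multiplier within
sampling error (the acceptance script measures the same recovery at 300
focal genes). The compactness ratio 0.1 reflects the sparse default genome
(150 genes on 4 Mb).

The same stages are available from the shell:

```sh
telocus simulate --seed 42 --out sim/
telocus partition --genes-gff sim/species0/genes.gff3 \
    --te-annotation sim/species0/tes.gff3 \
    --chrom-sizes sim/species0/chrom.sizes \
    --categories sim/species0/categories.tsv --out occupancy.tsv
telocus run-all --config pipeline.yaml --out report/
```

`run-all` writes the full table set (compartment occupancy, compactness,
species and per-category enrichment, hotspots, repeat landscape, family
sharing, expression contrast) plus a manifest with the config hash and
seed; reruns with the same config and seed are byte-identical.

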