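"""Chromosome compartment partitioning and per-locus TE profiling.

Each chromosome is partitioned into five disjoint compartments — exon,
intron, 5'-flank, 3'-flank and intergenic — with precedence
exon > intron > flank > intergenic.  Flanks extend ``flank_size`` bp (default
20 kb, the proximate-promoter scale) from the gene body; where two genes'
flanks collide, each base goes to the nearer gene (ties prefer the 5' flank).
Per-gene locus windows (gene body plus both flanks) are profiled for TE
coverage (union bp) and TE count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .annotation_io import (
    AnnotationError,
    ChromSpec,
    GeneModel,
    TEInsertion,
    TE_CLASSIFICATIONS,
    merge_intervals,
)

COMPARTMENT_LABELS = ("exon", "intron", "flank5", "flank3", "intergenic")

DEFAULT_FLANK_SIZE = 20_000


@dataclass
class CompartmentMap:
    """Disjoint labeled partition of one chromosome."""

    chrom: str
    length: int
    intervals: list[tuple[int, int, str]]

    def total_bp(self) -> dict[str, int]:
        totals = {label: 0 for label in COMPARTMENT_LABELS}
        for s, e, label in self.intervals:
            totals[label] += e - s
        return totals


@dataclass
class LocusWindow:
    """A gene body extended by one flank length on each side, clipped to the
    chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass
class LocusTEProfile:
    """TE occupancy of one gene's locus window.

    ``coverage_bp`` is the union of TE bp within the window; ``count`` is the
    number of distinct insertions with >= 1 bp overlap.  ``genic_te_bp`` is
    the TE union restricted to the gene body (used for TE-excised gene
    sizes).
    """

    gene_id: str
    coverage_bp: int
    count: int
    per_class: dict[str, tuple[int, int]] = field(default_factory=dict)
    window: tuple[int, int] | None = None
    genic_te_bp: int = 0


def _flank_label(strand: str, side: str) -> str:
    """Compartment label for the flank on a given coordinate side of a gene.

    ``side`` is 'left' (lower coordinates) or 'right'.  For a + strand gene
    the left flank is upstream (5'); for a - strand gene it is downstream (3').
    """
    if side == "left":
        return "flank5" if strand == "+" else "flank3"
    return "flank3" if strand == "+" else "flank5"


def build_compartment_map(
    genes: Sequence[GeneModel],
    chrom_spec: ChromSpec,
    flank_size: int = DEFAULT_FLANK_SIZE,
) -> CompartmentMap:
    """Partition one chromosome into exon/intron/flank/intergenic intervals.

    Only genes on ``chrom_spec.name`` are used.  Every base receives exactly
    one label; the returned intervals are sorted, disjoint, and cover
    ``[0, length)`` exactly.
    """
    L = chrom_spec.length
    chrom_genes = [g for g in genes if g.chrom == chrom_spec.name]
    for g in chrom_genes:
        if g.end > L or g.start < 0:
            raise AnnotationError(
                f"gene {g.gene_id} ({g.start}-{g.end}) outside chromosome "
                f"{chrom_spec.name} of length {L}"
            )
    if not chrom_genes:
        return CompartmentMap(chrom_spec.name, L, [(0, L, "intergenic")] if L else [])

    exon_union = merge_intervals([iv for g in chrom_genes for iv in g.exons])
    genic_union = merge_intervals([(g.start, g.end) for g in chrom_genes])

    labeled: list[tuple[int, int, str]] = []
    labeled.extend((s, e, "exon") for s, e in exon_union)
    for s, e in _difference(genic_union, exon_union):
        labeled.append((s, e, "intron"))

    # Non-genic gaps: assign flank labels by nearest gene across each gap.
    gap_edges = [0] + [x for s, e in genic_union for x in (s, e)] + [L]
    for g0, g1 in zip(gap_edges[::2], gap_edges[1::2]):
        if g0 >= g1:
            continue
        left_gene = _edge_gene(chrom_genes, end_at=g0) if g0 > 0 else None
        right_gene = _edge_gene(chrom_genes, start_at=g1) if g1 < L else None
        labeled.extend(_label_gap(g0, g1, left_gene, right_gene, flank_size))

    labeled.sort()
    return CompartmentMap(chrom_spec.name, L, _coalesce(labeled))


def _edge_gene(genes: Sequence[GeneModel], end_at: int | None = None,
               start_at: int | None = None) -> GeneModel:
    if end_at is not None:
        cands = [g for g in genes if g.end == end_at]
    else:
        cands = [g for g in genes if g.start == start_at]
    # Among co-terminal genes prefer the one whose flank would be 5' (ties ->
    # flank5 rule), then lexicographic id for determinism.
    side = "right" if end_at is not None else "left"
    cands.sort(key=lambda g: (_flank_label(g.strand, side) != "flank5", g.gene_id))
    return cands[0]


def _label_gap(
    g0: int, g1: int,
    left_gene: GeneModel | None, right_gene: GeneModel | None,
    flank_size: int,
) -> list[tuple[int, int, str]]:
    """Label one maximal non-genic gap [g0, g1)."""
    out: list[tuple[int, int, str]] = []
    left_lab = _flank_label(left_gene.strand, "right") if left_gene else None
    right_lab = _flank_label(right_gene.strand, "left") if right_gene else None
    left_zone_end = min(g1, g0 + flank_size) if left_gene else g0
    right_zone_start = max(g0, g1 - flank_size) if right_gene else g1

    if left_zone_end <= right_zone_start:
        if left_gene and left_zone_end > g0:
            out.append((g0, left_zone_end, left_lab))
        if left_zone_end < right_zone_start:
            out.append((left_zone_end, right_zone_start, "intergenic"))
        if right_gene and right_zone_start < g1:
            out.append((right_zone_start, g1, right_lab))
        return out

    # Contested region: nearest gene wins.  For base b, distance to the left
    # gene is b - g0 + 1 and to the right gene g1 - b; b belongs to the left
    # gene iff b - g0 + 1 < g1 - b, i.e. b < (g0 + g1 - 1) / 2; equality is a
    # tie, resolved in favor of whichever side is a 5' flank (left if both or
    # neither are).
    a, b = right_zone_start, left_zone_end  # overlap [a, b)
    tie2 = g0 + g1 - 1  # 2*b_tie
    split = (tie2 + 1) // 2  # first base NOT closer to the left gene
    has_tie = tie2 % 2 == 0
    tie_base = tie2 // 2 if has_tie else None
    if has_tie and right_lab == "flank5" and left_lab != "flank5":
        split = tie_base  # tie base goes right
    elif has_tie:
        split = tie_base + 1  # tie base goes left
    split = min(max(split, a), b)
    if g0 < a:
        out.append((g0, a, left_lab))
    if a < split:
        out.append((a, split, left_lab))
    if split < b:
        out.append((split, b, right_lab))
    if b < g1:
        out.append((b, g1, right_lab))
    return out


def _difference(base: list[tuple[int, int]], minus: list[tuple[int, int]]
                ) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(minus) and minus[j][1] <= s:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _coalesce(labeled: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for s, e, lab in labeled:
        if s >= e:
            continue
        if out and out[-1][1] == s and out[-1][2] == lab:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


# ---------------------------------------------------------------------------
# occupancy and locus profiles
# ---------------------------------------------------------------------------

def compartment_occupancy(
    cmaps: Sequence[CompartmentMap], tes: Sequence[TEInsertion]
):
    """TE bp per compartment label, absolute and as % of total genome size.

    TEs should be defragmented (and, for strict bp attribution, overlap
    resolved) first; bases covered by more than one TE are counted once.
    Returns a pandas DataFrame with columns label, te_bp, pct_genome.
    """
    import pandas as pd

    genome_len = sum(c.length for c in cmaps)
    te_union: dict[str, list[tuple[int, int]]] = {}
    for t in tes:
        te_union.setdefault(t.chrom, []).append((t.start, t.end))
    te_union = {c: merge_intervals(ivs) for c, ivs in te_union.items()}

    totals = {label: 0 for label in COMPARTMENT_LABELS}
    for cmap in cmaps:
        blocks = te_union.get(cmap.chrom, [])
        if not blocks:
            continue
        j = 0
        for s, e, lab in cmap.intervals:
            while j < len(blocks) and blocks[j][1] <= s:
                j += 1
            k = j
            while k < len(blocks) and blocks[k][0] < e:
                bs, be = blocks[k]
                totals[lab] += min(e, be) - max(s, bs)
                k += 1
    rows = [
        {"label": lab, "te_bp": totals[lab],
         "pct_genome": 100.0 * totals[lab] / genome_len if genome_len else 0.0}
        for lab in COMPARTMENT_LABELS
    ]
    return pd.DataFrame(rows)


def locus_windows(
    genes: Sequence[GeneModel],
    chrom_specs: Sequence[ChromSpec],
    flank_size: int = DEFAULT_FLANK_SIZE,
) -> list[LocusWindow]:
    lengths = {c.name: c.length for c in chrom_specs}
    windows = []
    for g in genes:
        L = lengths[g.chrom]
        windows.append(
            LocusWindow(g.gene_id, g.chrom, max(0, g.start - flank_size),
                        min(L, g.end + flank_size))
        )
    return windows


def profile_locus(
    genes: Sequence[GeneModel],
    tes: Sequence[TEInsertion],
    chrom_specs: Sequence[ChromSpec],
    flank_size: int = DEFAULT_FLANK_SIZE,
) -> list[LocusTEProfile]:
    """Profile TE coverage and count over each gene's locus window.

    A TE overlapping two gene windows contributes to both; one defragmented
    insertion counts once per window however many compartments it spans.
    Coverage is the union of clipped TE intervals; per-classification values
    are computed identically per class.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise AnnotationError(f"duplicate gene_id(s): {dup}")

    trees: dict[str, IntervalTree] = {}
    for idx, t in enumerate(tes):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, idx)

    profiles: list[LocusTEProfile] = []
    for g, w in zip(genes, locus_windows(genes, chrom_specs, flank_size)):
        tree = trees.get(g.chrom)
        hits = sorted(tree.overlap(w.start, w.end), key=lambda iv: iv.data) if tree else []
        clipped_all: list[tuple[int, int]] = []
        by_class: dict[str, list[tuple[int, int]]] = {}
        genic: list[tuple[int, int]] = []
        for iv in hits:
            t = tes[iv.data]
            c = (max(t.start, w.start), min(t.end, w.end))
            clipped_all.append(c)
            by_class.setdefault(t.classification, []).append(c)
            if t.start < g.end and t.end > g.start:
                genic.append((max(t.start, g.start), min(t.end, g.end)))
        coverage = _union_bp(clipped_all)
        per_class = {
            cls: (_union_bp(ivs), len(ivs)) for cls, ivs in sorted(by_class.items())
        }
        profiles.append(
            LocusTEProfile(
                gene_id=g.gene_id,
                coverage_bp=coverage,
                count=len(hits),
                per_class=per_class,
                window=(w.start, w.end),
                genic_te_bp=_union_bp(genic),
            )
        )
    return profiles


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals)) if intervals else 0


# ---------------------------------------------------------------------------
# genome compactness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompactnessResult:
    genic_bp: int
    intergenic_bp: int
    ratio: float          # raw genic/intergenic ratio (inf if intergenic == 0)
    ratio_rounded: float  # 2 decimals, round-half-even


def compactness_ratio(cmaps: Sequence[CompartmentMap]) -> CompactnessResult:
    """Genome compactness: genic (exon+intron) to intergenic (flanks +
    intergenic space) base-pair ratio."""
    if not cmaps:
        raise ValueError("at least one compartment map is required")
    genic = 0
    intergenic = 0
    for cmap in cmaps:
        totals = cmap.total_bp()
        genic += totals["exon"] + totals["intron"]
        intergenic += totals["flank5"] + totals["flank3"] + totals["intergenic"]
    if intergenic == 0:
        return CompactnessResult(genic, intergenic, float("inf"), float("inf"))
    ratio = genic / intergenic
    return CompactnessResult(genic, intergenic, ratio, round(ratio, 2))


def compactness_from_bp(genic_bp: float, intergenic_bp: float) -> CompactnessResult:
    """Compactness ratio directly from genic/intergenic bp totals."""
    if intergenic_bp == 0:
        return CompactnessResult(int(genic_bp), 0, float("inf"), float("inf"))
    ratio = genic_bp / intergenic_bp
    return CompactnessResult(int(genic_bp), int(intergenic_bp), ratio, round(ratio, 2))


def export_compartment_bed(cmaps: Sequence[CompartmentMap], path) -> None:
    from pathlib import Path

    lines = []
    for cmap in sorted(cmaps, key=lambda c: c.chrom):
        for s, e, lab in cmap.intervals:
            lines.append(f"{cmap.chrom}\t{s}\t{e}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")
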