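"""Annotation I/O: coordinate conventions, round-trips, defragmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import naive_defragment
from telocus.annotation_io import (
    AnnotationError,
    ChromSpec,
    GeneModel,
    TEInsertion,
    defragment,
    merge_intervals,
    normalize_classification,
    read_chrom_sizes,
    read_gene_gff,
    read_te_annotation,
    resolve_overlaps,
    write_chrom_sizes,
    write_gene_gff,
    write_te_bed,
    write_te_gff,
)

GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=gA
chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=gA
"""


class TestGeneGFF:
    def test_gff_one_based_closed_converts_to_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_ONE_GENE)
        (gene,) = read_gene_gff(p)
        assert gene.exons == [(0, 100)]
        assert gene.length == 100

    def test_bookended_exons_merge(self):
        g = GeneModel("g", "chr1", "+", [(0, 50), (50, 100)])
        assert g.exons == [(0, 100)]

    def test_category_from_table_and_default(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_ONE_GENE)
        (gene,) = read_gene_gff(p, {"gA": ("CYP", "insecticide")})
        assert (gene.category, gene.cyp_function) == ("CYP", "insecticide")
        (gene,) = read_gene_gff(p, {})
        assert (gene.category, gene.cyp_function) == ("other", "unassigned")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(AnnotationError, match=":2"):
            read_gene_gff(p)

    def test_exon_outside_chromosome_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_ONE_GENE)
        with pytest.raises(AnnotationError, match="beyond chromosome"):
            read_gene_gff(p, chrom_specs=[ChromSpec("chr1", 50)])

    def test_three_gene_round_trip(self, tmp_path):
        genes = [
            GeneModel("a", "chr1", "+", [(10, 50), (80, 120)], "CYP", "natural"),
            GeneModel("b", "chr1", "-", [(200, 260)], "HKG"),
            GeneModel("c", "chr2", "+", [(0, 30), (60, 95), (100, 140)], "UGT"),
        ]
        table = {g.gene_id: (g.category, g.cyp_function) for g in genes}
        p = tmp_path / "rt.gff3"
        write_gene_gff(genes, p)
        back = read_gene_gff(p, table)
        assert back == sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        # a second round-trip is byte-identical
        p2 = tmp_path / "rt2.gff3"
        write_gene_gff(back, p2)
        assert p.read_text() == p2.read_text()


class TestTEAnnotation:
    def test_bed_record(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t10\t20\tfam1\t0\t+\tDNA\n")
        (te,) = read_te_annotation(p)
        assert (te.start, te.end, te.length, te.classification) == (10, 20, 10, "DNA")

    def test_unknown_classification_maps_to_other(self, tmp_path, caplog):
        assert normalize_classification("Unknown/Foo") == ("Other", False)
        assert normalize_classification("DNA/hAT-Tip100") == ("DNA", True)
        assert normalize_classification("RC/Helitron") == ("RollingCircle", True)
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t5\tf\t0\t+\tWeirdClass\n")
        with caplog.at_level("WARNING"):
            (te,) = read_te_annotation(p)
        assert te.classification == "Other"
        assert "WeirdClass" in caplog.text

    def test_zero_length_interval_rejected(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t5\t5\tfam\n")
        with pytest.raises(AnnotationError, match="zero-length"):
            read_te_annotation(p)

    @pytest.mark.parametrize("writer,ext", [(write_te_gff, "gff3"), (write_te_bed, "bed")])
    def test_round_trip_preserves_records_and_bp(self, tmp_path, writer, ext):
        tes = [
            TEInsertion("chr1", 0, 500, "famA", "DNA", "+", 0.05),
            TEInsertion("chr1", 600, 700, "famA", "DNA", "-"),
            TEInsertion("chr1", 900, 2000, "famB", "LINE", "."),
            TEInsertion("chr2", 10, 30, "famC", "SINE", "+", 0.123456),
            TEInsertion("chr2", 25, 80, "famD", "PLE", "-", 0.4),
        ]
        p = tmp_path / f"t.{ext}"
        writer(tes, p)
        back = read_te_annotation(p)
        assert sum(t.length for t in back) == sum(t.length for t in tes)
        assert [(t.chrom, t.start, t.end, t.family_id, t.classification, t.strand)
                for t in back] == [
            (t.chrom, t.start, t.end, t.family_id, t.classification, t.strand) for t in tes
        ]

    def test_chrom_sizes_round_trip(self, tmp_path):
        specs = [ChromSpec("chr1", 1000), ChromSpec("chr2", 500)]
        p = tmp_path / "c.sizes"
        write_chrom_sizes(specs, p)
        assert read_chrom_sizes(p) == specs


class TestDefragment:
    def test_merge_within_gap(self):
        tes = [TEInsertion("chr1", 0, 100, "fam1", "DNA", "+"),
               TEInsertion("chr1", 150, 250, "fam1", "DNA", "+")]
        (merged,) = defragment(tes, max_gap=100)
        assert (merged.start, merged.end) == (0, 250)

    def test_no_merge_beyond_gap(self):
        tes = [TEInsertion("chr1", 0, 100, "fam1", "DNA", "+"),
               TEInsertion("chr1", 150, 250, "fam1", "DNA", "+")]
        assert len(defragment(tes, max_gap=40)) == 2

    def test_merged_divergence_is_length_weighted(self):
        tes = [TEInsertion("chr1", 0, 100, "f", "DNA", "+", divergence=0.1),
               TEInsertion("chr1", 100, 400, "f", "DNA", "+", divergence=0.3)]
        (m,) = defragment(tes, 50)
        assert m.divergence == pytest.approx((100 * 0.1 + 300 * 0.3) / 400)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            defragment([], max_gap=-1)

    @staticmethod
    def _random_tes(rng, n):
        fams = ["f1", "f2"]
        out = []
        for _ in range(n):
            s = int(rng.integers(0, 2_000))
            out.append(
                TEInsertion(
                    chrom=str(rng.choice(["chr1", "chr2"])), start=s,
                    end=s + int(rng.integers(1, 300)),
                    family_id=str(rng.choice(fams)),
                    classification="DNA", strand=str(rng.choice(["+", "-", "."])),
                )
            )
        out.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
        return out

    def test_matches_naive_transitive_merge(self, rng):
        for trial in range(50):
            tes = self._random_tes(rng, int(rng.integers(1, 25)))
            gap = int(rng.integers(0, 200))
            got = sorted(
                (t.chrom, t.family_id, t.strand, t.start, t.end) for t in defragment(tes, gap)
            )
            assert got == naive_defragment(tes, gap), f"trial {trial}, gap {gap}"

    def test_idempotent_and_bp_never_decreases(self, rng):
        for _ in range(25):
            tes = self._random_tes(rng, int(rng.integers(1, 25)))
            gap = int(rng.integers(0, 200))
            once = defragment(tes, gap)
            assert defragment(once, gap) == once
            before = sum(
                e - s for s, e in merge_intervals([(t.start, t.end) for t in tes])
            )
            after = sum(t.length for t in once)
            assert after >= before
            assert len(once) <= len(tes)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 1000),
                  st.integers(1, 200), st.sampled_from(["a", "b"]),
                  st.sampled_from(["+", "-"])),
        min_size=1, max_size=12,
    ), st.integers(0, 150))
    def test_never_merges_across_family_strand_or_chrom(self, specs, gap):
        tes = sorted(
            (TEInsertion(c, s, s + ln, f, "DNA", strand) for c, s, ln, f, strand in specs),
            key=lambda t: (t.chrom, t.start, t.end, t.family_id),
        )
        merged = defragment(tes, gap)
        # the naive left-to-right transitive merge (which by construction
        # never crosses families, strands or chromosomes) must agree exactly
        got = sorted(
            (t.chrom, t.family_id, t.strand, t.start, t.end) for t in merged
        )
        assert got == naive_defragment(tes, gap)
        # and merged intervals never span another chromosome's coordinates
        for m in merged:
            assert all(t.chrom == m.chrom for t in tes
                       if t.family_id == m.family_id and t.chrom == m.chrom)


class TestResolveOverlaps:
    def test_longer_copy_wins_shorter_truncated(self):
        tes = [TEInsertion("chr1", 0, 1000, "famA", "DNA", "+"),
               TEInsertion("chr1", 800, 1100, "famB", "LINE", "+")]
        out = resolve_overlaps(tes)
        assert (out[0].start, out[0].end, out[0].family_id) == (0, 1000, "famA")
        assert (out[1].start, out[1].end, out[1].family_id) == (1000, 1100, "famB")

    def test_no_double_counted_bp(self, rng):
        tes = TestDefragment._random_tes(rng, 20)
        out = resolve_overlaps(tes)
        ivs = sorted((t.chrom, t.start, t.end) for t in out)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or s2 >= e1
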