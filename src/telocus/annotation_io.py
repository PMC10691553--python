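"""Readers, writers, and domain records for gene and TE annotations.

All coordinates are held internally as 0-based half-open intervals
``[start, end)``.  GFF3 I/O converts from/to the 1-based closed convention at
the boundary; BED is already half-open and passes through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Gene category vocabulary.  The five xenobiotic gene families (XGFs) are the
#: detoxification families; HKG marks housekeeping genes used as a
#: chromatin-accessibility comparator; everything else is "other".
XGF_CATEGORIES = ("CYP", "GST", "esterase", "UGT", "ABC")
GENE_CATEGORIES = XGF_CATEGORIES + ("HKG", "other")

#: Functional labels for CYP genes: linked to xenobiotic detoxification in
#: general, to synthetic-insecticide or natural-compound resistance
#: specifically, to other functions, or unassigned.
CYP_FUNCTIONS = ("xenobiotic", "other", "insecticide", "natural", "unassigned")

#: Closed vocabulary of major TE classifications.
TE_CLASSIFICATIONS = ("DNA", "RollingCircle", "LINE", "SINE", "LTR", "PLE", "Other")

_CLASSIFICATION_ALIASES = {
    "dna": "DNA",
    "rollingcircle": "RollingCircle",
    "rc": "RollingCircle",
    "helitron": "RollingCircle",
    "line": "LINE",
    "sine": "SINE",
    "ltr": "LTR",
    "ple": "PLE",
    "penelope": "PLE",
    "other": "Other",
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class ChromSpec:
    """A chromosome (or scaffold) name and its length in bp."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"chromosome {self.name!r} has length {self.length} < 1")


@dataclass
class GeneModel:
    """A gene with exon structure, strand, and functional category label.

    The gene body spans ``[min exon start, max exon end)``; introns are the
    gaps between exons inside the body.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    category: str = "other"
    cyp_function: str = "unassigned"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.category not in GENE_CATEGORIES:
            raise AnnotationError(f"gene {self.gene_id}: unknown category {self.category!r}")
        if self.cyp_function not in CYP_FUNCTIONS:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown cyp_function {self.cyp_function!r}"
            )
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        self.exons = merge_intervals(self.exons)
        if self.exons[0][0] < 0:
            raise AnnotationError(f"gene {self.gene_id}: negative coordinate")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TEInsertion:
    """One annotated transposable-element interval.

    ``divergence`` is the Kimura two-parameter distance of the copy from its
    family consensus (a fraction, e.g. 0.05), or ``None`` when unknown.
    """

    chrom: str
    start: int
    end: int
    family_id: str
    classification: str = "Other"
    strand: str = "."
    divergence: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"TE {self.family_id} at {self.chrom}:{self.start}-{self.end}: empty interval"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"TE {self.family_id}: bad strand {self.strand!r}")
        if self.classification not in TE_CLASSIFICATIONS:
            raise AnnotationError(f"TE {self.family_id}: bad classification {self.classification!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExpressionRecord:
    """Read-count record for one gene in one tissue."""

    gene_id: str
    tissue: str
    read_count: int
    transcript_length: int
    library_size: int

    def __post_init__(self) -> None:
        if self.transcript_length < 1:
            raise AnnotationError(f"{self.gene_id}: transcript_length < 1")
        if self.read_count < 0 or self.library_size < self.read_count:
            raise AnnotationError(f"{self.gene_id}: invalid read/library counts")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort intervals and merge any that overlap or abut (bookended)."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise AnnotationError(f"interval ({s}, {e}) has start > end")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def normalize_classification(raw: str) -> tuple[str, bool]:
    """Map a free-text TE classification onto the closed vocabulary.

    Returns (classification, recognized).  Strings like ``DNA/hAT-Tip100`` are
    matched on their leading token; anything unrecognized maps to ``Other``.
    """
    token = re.split(r"[/?]", raw.strip())[0].strip().lower().replace("-", "").replace("_", "")
    if token in _CLASSIFICATION_ALIASES:
        return _CLASSIFICATION_ALIASES[token], True
    return "Other", False


# ---------------------------------------------------------------------------
# chromosome sizes and category tables
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> list[ChromSpec]:
    """Read a two-column (name, length) TSV; FASTA .fai files also work
    because only the first two columns are consulted."""
    specs: list[ChromSpec] = []
    seen: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{i}: expected at least 2 tab-separated columns")
        name = parts[0]
        if name in seen:
            raise AnnotationError(f"{path}:{i}: duplicate chromosome {name!r}")
        seen.add(name)
        specs.append(ChromSpec(name, int(parts[1])))
    return specs


def write_chrom_sizes(specs: Sequence[ChromSpec], path: str | Path) -> None:
    lines = [f"{s.name}\t{s.length}" for s in sorted(specs, key=lambda s: s.name)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_category_table(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV mapping gene_id -> (category, cyp_function).

    A header line is detected by the literal first column name ``gene_id``.
    The third column is optional and defaults to ``unassigned``.
    """
    table: dict[str, tuple[str, str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if i == 1 and parts[0] == "gene_id":
            continue
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{i}: expected gene_id<TAB>category")
        gene_id, category = parts[0], parts[1]
        cyp_function = parts[2] if len(parts) > 2 and parts[2] else "unassigned"
        if category not in GENE_CATEGORIES:
            raise AnnotationError(f"{path}:{i}: unknown category {category!r}")
        table[gene_id] = (category, cyp_function)
    return table


def write_category_table(
    table: Mapping[str, tuple[str, str]], path: str | Path
) -> None:
    lines = ["gene_id\tcategory\tcyp_function"]
    for gid in sorted(table):
        cat, fn = table[gid]
        lines.append(f"{gid}\t{cat}\t{fn}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gene_gff(
    path: str | Path,
    category_table: Mapping[str, tuple[str, str]] | None = None,
    chrom_specs: Sequence[ChromSpec] | None = None,
) -> list[GeneModel]:
    """Read gene models from a GFF3 with ``gene`` and ``exon`` features.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Genes absent from ``category_table`` get category ``other``.  When
    ``chrom_specs`` is given, exons outside the declared chromosome bounds
    raise :class:`AnnotationError`.
    """
    category_table = category_table or {}
    lengths = {c.name: c.length for c in chrom_specs} if chrom_specs else None
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[str, int, int]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != _GFF_COLS:
            raise AnnotationError(f"{path}:{i}: expected {_GFF_COLS} columns, got {len(parts)}")
        chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = parts
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{i}: non-integer coordinates") from exc
        if start1 < 1 or end1 < start1:
            raise AnnotationError(f"{path}:{i}: bad coordinate range {start1}-{end1}")
        start, end = start1 - 1, end1  # GFF3 -> half-open
        attrs = _parse_attributes(attr_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise AnnotationError(f"{path}:{i}: gene feature without ID attribute")
            genes[gid] = {"chrom": chrom, "strand": strand, "line": i}
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise AnnotationError(f"{path}:{i}: exon feature without Parent attribute")
            if lengths is not None:
                if chrom not in lengths:
                    raise AnnotationError(f"{path}:{i}: unknown chromosome {chrom!r}")
                if end > lengths[chrom]:
                    raise AnnotationError(
                        f"{path}:{i}: exon end {end} beyond chromosome {chrom} "
                        f"length {lengths[chrom]}"
                    )
            exons.setdefault(parent, []).append((chrom, start, end))

    models: list[GeneModel] = []
    for gid, info in genes.items():
        gene_exons = exons.get(gid)
        if not gene_exons:
            raise AnnotationError(f"{path}: gene {gid} (line {info['line']}) has no exons")
        if any(c != info["chrom"] for c, _s, _e in gene_exons):
            raise AnnotationError(f"{path}: gene {gid} has exons on a different chromosome")
        category, cyp_function = category_table.get(gid, ("other", "unassigned"))
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=[(s, e) for _c, s, e in gene_exons],
                category=category,
                cyp_function=cyp_function,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def write_gene_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as sorted, deterministic GFF3 (gene + exon rows)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(
            "\t".join(
                [g.chrom, "telocus", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for k, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                "\t".join(
                    [g.chrom, "telocus", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", f"ID={g.gene_id}.exon{k};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TE annotations (GFF3 or BED6+)
# ---------------------------------------------------------------------------

def read_te_annotation(
    path: str | Path, chrom_specs: Sequence[ChromSpec] | None = None
) -> list[TEInsertion]:
    """Read TE insertions from GFF3 or BED6+.

    The format is sniffed: files whose data rows have 9 columns with a
    ``key=value`` attribute field are treated as GFF3, otherwise as BED
    (columns: chrom start end family score strand [classification]
    [divergence]).  Unknown classification strings map to ``Other`` with a
    logged warning; zero-length intervals are rejected.
    """
    lengths = {c.name: c.length for c in chrom_specs} if chrom_specs else None
    tes: list[TEInsertion] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        is_gff = len(parts) == 9 and "=" in parts[8]
        if is_gff:
            chrom, _src, _ftype, start_s, end_s, _score, strand, _frame, attr_s = parts
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: non-integer coordinates") from exc
            attrs = _parse_attributes(attr_s)
            family = attrs.get("family_id") or attrs.get("Family") or attrs.get("Name")
            if family is None:
                raise AnnotationError(f"{path}:{i}: TE record without family attribute")
            raw_class = attrs.get("classification") or attrs.get("Classification") or "Other"
            div_s = attrs.get("divergence") or attrs.get("Divergence")
        else:
            if len(parts) < 4:
                raise AnnotationError(f"{path}:{i}: BED record needs >= 4 columns")
            chrom, start_s, end_s, family = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] else "."
            raw_class = parts[6] if len(parts) > 6 and parts[6] else "Other"
            div_s = parts[7] if len(parts) > 7 and parts[7] not in ("", ".") else None
        if start >= end:
            raise AnnotationError(f"{path}:{i}: zero-length TE interval")
        if lengths is not None and chrom in lengths and end > lengths[chrom]:
            raise AnnotationError(f"{path}:{i}: TE beyond chromosome {chrom} bounds")
        classification, known = normalize_classification(raw_class)
        if not known:
            logger.warning("%s:%d: unknown TE classification %r mapped to Other", path, i, raw_class)
        divergence = float(div_s) if div_s is not None else None
        tes.append(
            TEInsertion(
                chrom=chrom, start=start, end=end, family_id=family,
                classification=classification, strand=strand, divergence=divergence,
            )
        )
    tes.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
    return tes


def write_te_gff(tes: Sequence[TEInsertion], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for t in sorted(tes, key=lambda t: (t.chrom, t.start, t.end, t.family_id)):
        attrs = f"family_id={t.family_id};classification={t.classification}"
        if t.divergence is not None:
            attrs += f";divergence={t.divergence:.6f}"
        lines.append(
            "\t".join(
                [t.chrom, "telocus", "dispersed_repeat", str(t.start + 1), str(t.end),
                 ".", t.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_te_bed(tes: Sequence[TEInsertion], path: str | Path) -> None:
    lines = []
    for t in sorted(tes, key=lambda t: (t.chrom, t.start, t.end, t.family_id)):
        div = f"{t.divergence:.6f}" if t.divergence is not None else "."
        lines.append(
            "\t".join(
                [t.chrom, str(t.start), str(t.end), t.family_id, "0", t.strand,
                 t.classification, div]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# defragmentation / overlap resolution
# ---------------------------------------------------------------------------

def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def defragment(tes: Sequence[TEInsertion], max_gap: int = 200) -> list[TEInsertion]:
    """Merge fragments likely to originate from one TE insertion.

    Consecutive insertions of the same family on the same chromosome whose
    gap is at most ``max_gap`` bp are merged (left to right, transitively)
    when their strands are compatible ('.' matches either strand).  The
    merged divergence is the length-weighted mean of the known fragment
    divergences.  Overlapping same-family fragments are unioned, so total
    covered bp never decreases.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    by_group: dict[tuple[str, str], list[TEInsertion]] = {}
    for t in tes:
        by_group.setdefault((t.chrom, t.family_id), []).append(t)
    out: list[TEInsertion] = []
    for group in by_group.values():
        group.sort(key=lambda t: (t.start, t.end, t.strand))
        cur = replace(group[0])
        cur_weights: list[tuple[int, float | None]] = [(cur.length, cur.divergence)]
        for t in group[1:]:
            if t.start - cur.end <= max_gap and _strand_compatible(cur.strand, t.strand):
                cur.end = max(cur.end, t.end)
                if cur.strand == ".":
                    cur.strand = t.strand
                cur_weights.append((t.length, t.divergence))
            else:
                cur.divergence = _weighted_divergence(cur_weights)
                out.append(cur)
                cur = replace(t)
                cur_weights = [(t.length, t.divergence)]
        cur.divergence = _weighted_divergence(cur_weights)
        out.append(cur)
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
    return out


def _weighted_divergence(weights: list[tuple[int, float | None]]) -> float | None:
    known = [(w, d) for w, d in weights if d is not None]
    if not known:
        return None
    total = sum(w for w, _d in known)
    return sum(w * d for w, d in known) / total


def resolve_overlaps(tes: Sequence[TEInsertion]) -> list[TEInsertion]:
    """Resolve overlaps between insertions of *different* families.

    The longer copy keeps its full span; shorter copies are truncated to the
    unoccupied remainder (pieces shorter than 1 bp vanish; a copy split in
    the middle yields one piece per remaining segment).  Same-family overlaps
    should be removed first with :func:`defragment`.
    """
    order = sorted(
        tes, key=lambda t: (-(t.length), t.chrom, t.start, t.family_id)
    )
    occupied: dict[str, list[tuple[int, int]]] = {}
    out: list[TEInsertion] = []
    for t in order:
        occ = occupied.setdefault(t.chrom, [])
        pieces = _subtract(t.start, t.end, occ)
        for s, e in pieces:
            out.append(replace(t, start=s, end=e))
        occ.extend(pieces)
        occupied[t.chrom] = merge_intervals(occ)
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
    return out


def _subtract(start: int, end: int, blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = [(start, end)]
    for bs, be in blocks:
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if be <= s or bs >= e:
                nxt.append((s, e))
                continue
            if s < bs:
                nxt.append((s, bs))
            if be < e:
                nxt.append((be, e))
        pieces = nxt
        if not pieces:
            break
    return pieces
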