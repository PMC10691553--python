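"""Greedy 80/80 clustering of TE-family consensus sequences across species.

Two consensus sequences belong to one family when they align locally at
>= 80% identity over >= 80% of the shorter sequence (the classic 80/80
family rule).  Clustering is greedy over length-descending input: each
sequence joins the best qualifying existing cluster representative or founds
a new cluster, mirroring CD-HIT-EST semantics with -c 0.8 -aS 0.8 -g 1 -r 1
(both strands searched).  Alignment is exact local alignment (match +1,
mismatch -1, gap open -2, gap extend -1) rather than a word-filter
heuristic: exact scoring is tractable at consensus-library scale and makes
the rule reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -2
GAP_EXTEND = -1


@dataclass(frozen=True)
class TEFamilyConsensus:
    """One species' consensus sequence for one TE family."""

    family_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.family_id}/{self.species_id}: empty sequence")

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.species_id)


@dataclass
class FamilyCluster:
    """A cross-species cluster of consensus sequences.

    ``sharing`` is the number of *other* species represented in the cluster:
    0 marks a species-specific family, n_species - 1 a family found in every
    species.
    """

    representative: tuple[str, str]
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sharing(self) -> int:
        return len({sp for _fam, sp in self.members}) - 1

    @property
    def species(self) -> set[str]:
        return {sp for _fam, sp in self.members}


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def identity_over_shorter(a_seq: str, b_seq: str) -> tuple[float, float]:
    """Best-strand local alignment identity and shorter-sequence coverage.

    Identity is matches / aligned columns (gap columns included); coverage is
    the aligned span on the shorter sequence divided by its length.  Both the
    given orientation and the reverse complement of ``b_seq`` are searched.
    Returns ``(identity, coverage)``; (0, 0) when no positive-scoring local
    alignment exists.
    """
    a_seq, b_seq = a_seq.upper(), b_seq.upper()
    best = None
    for candidate in (b_seq, reverse_complement(b_seq)):
        alns = _ALIGNER.align(a_seq, candidate)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        return 0.0, 0.0
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    # aligned span on each sequence, from the aligned block coordinates
    blocks_a, blocks_b = best.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0]) if len(blocks_a) else 0
    span_b = int(max(x for seg in blocks_b for x in seg) -
                 min(x for seg in blocks_b for x in seg)) if len(blocks_b) else 0
    if len(a_seq) <= len(b_seq):
        coverage = span_a / len(a_seq)
    else:
        coverage = span_b / len(b_seq)
    return identity, coverage


def _could_qualify(a_seq: str, b_seq: str, c: float, aS: float) -> bool:
    """Exact-bound prescreen: can ANY alignment of the pair satisfy the
    identity/coverage thresholds?

    A qualifying alignment (identity >= c over columns covering >= aS of the
    shorter sequence) implies an infix (HW-mode) edit distance of the shorter
    against the longer of at most ((1-c)/c + (1-aS)) * L_short: within-
    alignment mismatch and gap columns number at most (1-c)/c * L_short, and
    the uncovered shorter-sequence ends cost at most (1-aS) * L_short.
    Pairs beyond that bound (either strand) cannot qualify and are rejected
    without dynamic programming; this is a provable bound, not cd-hit's
    word-count heuristic.
    """
    if len(a_seq) <= len(b_seq):
        query, target = a_seq, b_seq
    else:
        query, target = b_seq, a_seq
    k = int(((1.0 - c) / c + (1.0 - aS)) * len(query)) + 1
    for t in (target, reverse_complement(target)):
        if edlib.align(query, t, mode="HW", task="distance", k=k)["editDistance"] != -1:
            return True
    return False


def greedy_cluster(
    consensi: Sequence[TEFamilyConsensus],
    c: float = 0.8,
    aS: float = 0.8,
    by_name: bool = False,
) -> list[FamilyCluster]:
    """Greedy clustering of consensus sequences under the 80/80 rule.

    Sequences are processed by length descending (ties: family then species
    id).  Each sequence joins the qualifying representative with the highest
    identity (ties: longest representative, then lexicographic id) or founds
    a new cluster.  With ``by_name=True``, entries sharing a family_id are
    pre-grouped without alignment (for curated reference families that carry
    one library name across species); the longest entry represents the group.
    """
    if not consensi:
        raise ValueError("at least one consensus is required")
    seqs = {x.key: x for x in consensi}
    if len(seqs) != len(consensi):
        raise ValueError("(family_id, species_id) pairs must be unique")

    pregroups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    units: list[TEFamilyConsensus] = []
    if by_name:
        by_fam: dict[str, list[TEFamilyConsensus]] = {}
        for x in consensi:
            by_fam.setdefault(x.family_id, []).append(x)
        for fam, group in by_fam.items():
            rep = max(group, key=lambda x: (len(x.sequence), x.species_id))
            units.append(rep)
            pregroups[rep.key] = [x.key for x in group]
    else:
        units = list(consensi)
        pregroups = {x.key: [x.key] for x in consensi}

    order = sorted(units, key=lambda x: (-len(x.sequence), x.family_id, x.species_id))
    clusters: list[FamilyCluster] = []
    reps: list[TEFamilyConsensus] = []
    for x in order:
        best_idx = None
        best_key = None
        for idx, rep in enumerate(reps):
            if not _could_qualify(rep.sequence, x.sequence, c, aS):
                continue
            identity, coverage = identity_over_shorter(rep.sequence, x.sequence)
            if identity >= c and coverage >= aS:
                key = (identity, len(rep.sequence), rep.family_id, rep.species_id)
                # highest identity, then longest representative, then id order
                if best_key is None or (
                    key[0] > best_key[0]
                    or (key[0] == best_key[0] and key[1] > best_key[1])
                    or (key[0] == best_key[0] and key[1] == best_key[1]
                        and (key[2], key[3]) < (best_key[2], best_key[3]))
                ):
                    best_key = key
                    best_idx = idx
        if best_idx is None:
            clusters.append(FamilyCluster(representative=x.key, members=list(pregroups[x.key])))
            reps.append(x)
        else:
            clusters[best_idx].members.extend(pregroups[x.key])
    for cl in clusters:
        cl.members.sort()
    return clusters


def sharing_profile(
    clusters: Sequence[FamilyCluster], species_list: Sequence[str]
):
    """Per-species percentage of families at each sharing level.

    Row ``sp``, column ``k`` holds the percentage of species ``sp``'s families
    that are shared with exactly ``k`` other species (k = 0 .. n_species-1).
    Rows sum to 100 for species with >= 1 family; a species with none yields a
    zero row with a logged warning.
    """
    import numpy as np
    import pandas as pd

    n = len(species_list)
    counts = {sp: np.zeros(n) for sp in species_list}
    for cl in clusters:
        k = cl.sharing
        fams_per_species: dict[str, int] = {}
        for _fam, sp in cl.members:
            fams_per_species[sp] = fams_per_species.get(sp, 0) + 1
        for sp, nf in fams_per_species.items():
            if sp in counts:
                counts[sp][k] += nf
    rows = {}
    for sp in species_list:
        total = counts[sp].sum()
        if total == 0:
            logger.warning("species %s has zero TE families", sp)
            rows[sp] = counts[sp]
        else:
            rows[sp] = 100.0 * counts[sp] / total
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"shared_{k}" for k in range(n)]
    ).rename_axis("species")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_consensus_fasta(
    path: str | Path, species_id: str | None = None
) -> list[TEFamilyConsensus]:
    """Read a consensus library FASTA.

    When ``species_id`` is None, headers are expected as
    ``species|family_id``; otherwise the whole header is the family id.
    """
    out: list[TEFamilyConsensus] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if species_id is None:
            if "|" not in rec.id:
                raise ValueError(f"{path}: header {rec.id!r} lacks 'species|family' form")
            sp, fam = rec.id.split("|", 1)
        else:
            sp, fam = species_id, rec.id
        out.append(TEFamilyConsensus(family_id=fam, species_id=sp, sequence=str(rec.seq)))
    return out


def write_consensus_fasta(consensi: Sequence[TEFamilyConsensus], path: str | Path) -> None:
    lines = []
    for x in sorted(consensi, key=lambda x: (x.species_id, x.family_id)):
        lines.append(f">{x.species_id}|{x.family_id}")
        seq = x.sequence
        lines.extend(seq[i:i + 80] for i in range(0, len(seq), 80))
    Path(path).write_text("\n".join(lines) + "\n")


def write_cluster_table(
    clusters: Sequence[FamilyCluster], path: str | Path
) -> None:
    lines = ["cluster\trepresentative\tfamily_id\tspecies_id\tsharing"]
    ordered = sorted(clusters, key=lambda cl: cl.representative)
    for i, cl in enumerate(ordered):
        rep = "|".join(cl.representative)
        for fam, sp in cl.members:
            lines.append(f"cluster{i}\t{rep}\t{fam}\t{sp}\t{cl.sharing}")
    Path(path).write_text("\n".join(lines) + "\n")
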