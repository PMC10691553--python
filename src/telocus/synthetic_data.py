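"""Synthetic multi-species genome annotations with planted TE structure.

The generator emits, per species: chromosome sizes, gene models with
exon/intron structure and category labels (five detoxification families, a
housekeeping panel, and background genes), TE insertions placed by a
Poisson process, per-species consensus libraries with controlled
cross-species sharing, and germline expression counts.  Enrichment at focal
gene sets is planted *mechanically*: the insertion rate inside focal locus
windows is multiplied by a planted count multiplier and insertion lengths
are scaled for the coverage multiplier, so the pipeline's estimators are
tested against a generative truth rather than post-hoc labels.

Defaults emulate the broad features of aphid-scale repeat biology at desk
scale: a DNA-transposon-dominant classification mixture, a heavy
right-skewed (log-normal) fragment-length distribution with mean 536 bp, a
genome-wide TE fraction near 13%, mostly recent TE activity, and a family
pool that is roughly half species-specific with a small universally shared
core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from types import SimpleNamespace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation_io import (
    ChromSpec,
    ExpressionRecord,
    GeneModel,
    TEInsertion,
    write_category_table,
    write_chrom_sizes,
    write_gene_gff,
    write_te_gff,
)
from .expression import write_expression_tsv
from .family_clustering import TEFamilyConsensus, write_consensus_fasta
from .te_divergence import PairwiseAlignment

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _default_classification_mix() -> dict[str, float]:
    # DNA share anchored at 45.27% (the dominant classification); remaining
    # classes carry plausible shares of an insect repeat complement.
    return {
        "DNA": 0.4527,
        "RollingCircle": 0.12,
        "LINE": 0.18,
        "LTR": 0.10,
        "SINE": 0.005,
        "PLE": 0.03,
        "Other": 0.1123,
    }


def _default_category_fractions() -> dict[str, float]:
    return {"CYP": 0.02, "GST": 0.02, "esterase": 0.02, "UGT": 0.02,
            "ABC": 0.02, "HKG": 0.02}


@dataclass
class SimConfig:
    """Parameters of the synthetic genome generator.

    Enrichment multipliers map gene category -> (coverage multiplier, count
    multiplier); categories not listed are unenriched.  The same seed always
    yields byte-identical output files.
    """

    seed: int = 0
    n_species: int = 3
    chrom_lengths: tuple[int, ...] = (2_000_000, 2_000_000)
    n_genes: int = 150
    mean_exons_per_gene: float = 3.0
    exon_length_mean: float = 300.0
    intron_length_mean: float = 700.0
    category_fractions: dict[str, float] = field(default_factory=_default_category_fractions)
    cyp_function_fractions: dict[str, float] = field(
        default_factory=lambda: {"insecticide": 0.3, "natural": 0.3, "other": 0.4}
    )
    te_rate_per_mb: float = 250.0
    te_length_mean: float = 536.0
    te_length_sigma: float = 1.0
    te_classification_mix: dict[str, float] = field(default_factory=_default_classification_mix)
    enrichment: dict[str, tuple[float, float]] = field(default_factory=dict)
    flank_size: int = 20_000
    n_families: int = 40
    fraction_families_universal: float = 0.10
    fraction_families_unique: float = 0.47
    consensus_length_range: tuple[int, int] = (300, 900)
    fraction_recent_families: float = 0.7
    recent_age_range: tuple[float, float] = (0.01, 0.10)
    old_age_range: tuple[float, float] = (0.20, 0.40)
    shared_family_offset_range: tuple[float, float] = (0.025, 0.10)
    hkg_rpkm_mean: float = 50.0
    xgf_rpkm_mean: float = 5.0
    other_rpkm_mean: float = 20.0
    library_size: int = 2_000_000
    cpg_mutation_factor: float = 10.0

    def validate(self) -> None:
        if self.n_species < 1 or self.n_genes < 1 or not self.chrom_lengths:
            raise ValueError("n_species, n_genes and chrom_lengths must be positive")
        for frac in list(self.category_fractions.values()) + [
            self.fraction_families_universal, self.fraction_families_unique,
            self.fraction_recent_families,
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for cov, cnt in self.enrichment.values():
            if cov <= 0 or cnt <= 0:
                raise ValueError("enrichment multipliers must be positive")


@dataclass
class SpeciesData:
    species_id: str
    chrom_specs: list[ChromSpec]
    genes: list[GeneModel]
    tes: list[TEInsertion]
    category_table: dict[str, tuple[str, str]]
    consensi: list[TEFamilyConsensus]
    expression: list[ExpressionRecord]


@dataclass
class SimulatedGenome:
    config: SimConfig
    species: dict[str, SpeciesData]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp_id, sp in self.species.items():
            d = outdir / sp_id
            d.mkdir(exist_ok=True)
            write_chrom_sizes(sp.chrom_specs, d / "chrom.sizes")
            write_gene_gff(sp.genes, d / "genes.gff3")
            write_te_gff(sp.tes, d / "tes.gff3")
            write_category_table(sp.category_table, d / "categories.tsv")
            write_consensus_fasta(sp.consensi, d / "consensus.fasta")
            if sp.expression:
                write_expression_tsv(sp.expression, d / "expression.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence mutation helpers
# ---------------------------------------------------------------------------

def kimura_rates_for_distance(d: float, ts_tv_ratio: float = 2.0) -> tuple[float, float]:
    """Transition/transversion fractions (p, q) whose Kimura 2P distance is
    ``d``, holding p/q at ``ts_tv_ratio``."""
    if d <= 0:
        return 0.0, 0.0
    k = ts_tv_ratio

    def f(p: float) -> float:
        q = p / k
        return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q)) - d

    hi = 0.999 / (2 + 1 / k)
    p = brentq(f, 1e-12, hi - 1e-9)
    return p, p / k


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))

def mutate_sequence(
    seq: str,
    d: float,
    rng: np.random.Generator,
    cpg_factor: float = 1.0,
) -> str:
    """Substitution-only mutated copy of ``seq`` at Kimura distance ``d``.

    Transitions at CpG dinucleotides of ``seq`` occur at ``cpg_factor``
    times the background transition rate, emulating CpG hypermutability (the
    convention the 1/10 CpG down-weighting of the divergence estimator
    corrects for).  No indels are introduced, so the copy aligns positionally
    to the template.
    """
    p, q = kimura_rates_for_distance(d)
    chars = list(seq.upper())
    n = len(chars)
    is_cpg = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if chars[i] == "C" and chars[i + 1] == "G":
            is_cpg[i] = is_cpg[i + 1] = True
    u = rng.random(n)
    v = rng.random(n)
    out = []
    for i, base in enumerate(chars):
        if base not in _TRANSITION:
            out.append(base)
            continue
        pt = min(cpg_factor * p, 0.45) if is_cpg[i] else p
        if u[i] < pt:
            out.append(_TRANSITION[base])
        elif u[i] < pt + q:
            out.append(_TRANSVERSIONS[base][int(v[i] < 0.5)])
        else:
            out.append(base)
    return "".join(out)


def simulate_copy_alignments(
    consensus: str,
    divergences: Sequence[float],
    rng: np.random.Generator,
    cpg_factor: float = 10.0,
) -> list[PairwiseAlignment]:
    """Generate gapless copy alignments of a consensus at given divergences."""
    return [
        PairwiseAlignment(consensus, mutate_sequence(consensus, d, rng, cpg_factor))
        for d in divergences
    ]


# ---------------------------------------------------------------------------
# family pool
# ---------------------------------------------------------------------------

def _build_family_pool(config: SimConfig, rng: np.random.Generator) -> list[SimpleNamespace]:
    """Global TE family pool with planted cross-species sharing.

    Each family carries a classification, an age (divergence scale of its
    copies), an archetype consensus, and the set of species that host it.
    """
    species_ids = [f"species{i}" for i in range(config.n_species)]
    n_universal = max(1, round(config.fraction_families_universal * config.n_families))
    n_unique = round(config.fraction_families_unique * config.n_families)
    n_partial = max(0, config.n_families - n_universal - n_unique)

    memberships: list[list[str]] = []
    memberships.extend([list(species_ids)] * n_universal)
    remaining = {sp: n_partial for sp in species_ids}
    while True:
        open_sp = [sp for sp in species_ids if remaining[sp] > 0]
        if len(open_sp) < 2 or config.n_species < 3:
            for sp in open_sp:
                memberships.extend([[sp]] * remaining[sp])
                remaining[sp] = 0
            break
        kmax = min(len(open_sp), config.n_species - 1)
        k = int(rng.integers(2, kmax + 1)) if kmax >= 2 else 2
        chosen = list(rng.choice(open_sp, size=k, replace=False))
        memberships.append(sorted(chosen))
        for sp in chosen:
            remaining[sp] -= 1
    for sp in species_ids:
        memberships.extend([[sp]] * n_unique)

    mix = config.te_classification_mix
    classes = sorted(mix)
    weights = np.array([mix[c] for c in classes], dtype=float)
    weights = weights / weights.sum()

    pool = []
    for i, members in enumerate(memberships):
        cls = str(rng.choice(classes, p=weights))
        recent = rng.random() < config.fraction_recent_families
        lo, hi = config.recent_age_range if recent else config.old_age_range
        age = float(rng.uniform(lo, hi))
        length = int(rng.integers(*config.consensus_length_range))
        archetype = random_sequence(length, rng)
        pool.append(
            SimpleNamespace(
                family_id=f"TEfam{i:04d}", classification=cls, age=age,
                species=members, archetype=archetype,
            )
        )
    return pool


# ---------------------------------------------------------------------------
# per-species simulation
# ---------------------------------------------------------------------------

def _simulate_genes(
    config: SimConfig, rng: np.random.Generator, species_id: str
) -> tuple[list[ChromSpec], list[GeneModel], dict[str, tuple[str, str]]]:
    chroms = [ChromSpec(f"chr{i+1}", L) for i, L in enumerate(config.chrom_lengths)]
    total_len = sum(c.length for c in chroms)
    counts = [round(config.n_genes * c.length / total_len) for c in chroms]
    counts[-1] += config.n_genes - sum(counts)

    # category assignment, deterministic proportions then shuffled
    labels: list[str] = []
    for cat, frac in sorted(config.category_fractions.items()):
        labels.extend([cat] * round(frac * config.n_genes))
    labels.extend(["other"] * (config.n_genes - len(labels)))
    labels = list(rng.permutation(labels))

    cyp_labels = sorted(config.cyp_function_fractions)
    cyp_w = np.array([config.cyp_function_fractions[k] for k in cyp_labels])
    cyp_w = cyp_w / cyp_w.sum()

    genes: list[GeneModel] = []
    table: dict[str, tuple[str, str]] = {}
    gi = 0
    for chrom, n in zip(chroms, counts):
        structures = []
        for _ in range(n):
            k = 1 + int(rng.poisson(config.mean_exons_per_gene - 1))
            exon_lens = np.maximum(
                30, rng.lognormal(math.log(config.exon_length_mean) - 0.125, 0.5, size=k)
            ).astype(int)
            intron_lens = np.maximum(
                50, rng.lognormal(math.log(config.intron_length_mean) - 0.32, 0.8, size=k - 1)
            ).astype(int)
            structures.append((exon_lens, intron_lens))
        occupied = sum(int(e.sum() + i.sum()) for e, i in structures)
        free = chrom.length - occupied - (n + 1)
        if free < 0:
            raise ValueError(
                f"infeasible packing: {occupied} gene bp exceed chromosome "
                f"{chrom.name} of length {chrom.length}"
            )
        gaps = (rng.dirichlet(np.ones(n + 1)) * free).astype(int) + 1
        pos = 0
        for (exon_lens, intron_lens), gap in zip(structures, gaps[:-1]):
            pos += int(gap)
            exons = []
            p = pos
            for j, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if j < len(intron_lens):
                    p += int(intron_lens[j])
            cat = labels[gi]
            cyp_fn = (
                str(rng.choice(cyp_labels, p=cyp_w)) if cat == "CYP" else "unassigned"
            )
            gid = f"{species_id}_g{gi:04d}"
            genes.append(
                GeneModel(gene_id=gid, chrom=chrom.name,
                          strand="+" if rng.random() < 0.5 else "-",
                          exons=exons, category=cat, cyp_function=cyp_fn)
            )
            table[gid] = (cat, cyp_fn)
            pos = p
            gi += 1
    return chroms, genes, table


def _focal_segments(
    chrom: ChromSpec,
    genes: Sequence[GeneModel],
    config: SimConfig,
) -> list[tuple[int, int, float, float]]:
    """Piecewise-constant (start, end, count_mult, length_scale) covering the
    chromosome.  Overlapping focal windows take the strongest count
    multiplier."""
    L = chrom.length
    boundaries = {0, L}
    windows = []
    for g in genes:
        if g.chrom != chrom.name or g.category not in config.enrichment:
            continue
        cov, cnt = config.enrichment[g.category]
        s = max(0, g.start - config.flank_size)
        e = min(L, g.end + config.flank_size)
        windows.append((s, e, cnt, cov / cnt))
        boundaries.update((s, e))
    edges = sorted(boundaries)
    segments = []
    for s, e in zip(edges, edges[1:]):
        cnt_mult, len_scale = 1.0, 1.0
        for ws, we, wc, wl in windows:
            if ws < e and we > s and wc >= cnt_mult:
                cnt_mult, len_scale = wc, wl
        segments.append((s, e, cnt_mult, len_scale))
    return segments


def _simulate_tes(
    config: SimConfig,
    rng: np.random.Generator,
    chroms: Sequence[ChromSpec],
    genes: Sequence[GeneModel],
    families: Sequence[SimpleNamespace],
) -> list[TEInsertion]:
    # per-family sampling weights: classification mix split evenly among the
    # species' families of that classification
    by_class: dict[str, list[SimpleNamespace]] = {}
    for fam in families:
        by_class.setdefault(fam.classification, []).append(fam)
    fam_list = list(families)
    weights = np.array(
        [config.te_classification_mix.get(f.classification, 0.0)
         / len(by_class[f.classification]) for f in fam_list]
    )
    if weights.sum() == 0:
        weights = np.ones(len(fam_list))
    weights = weights / weights.sum()

    lam = config.te_rate_per_mb / 1e6
    mu = math.log(config.te_length_mean) - config.te_length_sigma ** 2 / 2.0
    tes: list[TEInsertion] = []
    for chrom in chroms:
        for s, e, cnt_mult, len_scale in _focal_segments(chrom, genes, config):
            n = int(rng.poisson(lam * cnt_mult * (e - s)))
            if n == 0:
                continue
            starts = np.sort(rng.integers(s, e, size=n))
            lens = np.maximum(
                20, (rng.lognormal(mu, config.te_length_sigma, size=n) * len_scale)
            ).astype(int)
            fam_idx = rng.choice(len(fam_list), size=n, p=weights)
            age_jitter = rng.uniform(0.7, 1.3, size=n)
            strands = rng.random(n) < 0.5
            for st, ln, fi, jit, plus in zip(starts, lens, fam_idx, age_jitter, strands):
                fam = fam_list[fi]
                tes.append(
                    TEInsertion(
                        chrom=chrom.name, start=int(st),
                        end=int(min(chrom.length, st + ln)),
                        family_id=fam.family_id,
                        classification=fam.classification,
                        strand="+" if plus else "-",
                        divergence=min(max(fam.age * float(jit), 1e-3), 0.49),
                    )
                )
    tes.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
    return tes


def _simulate_expression(
    config: SimConfig, rng: np.random.Generator, genes: Sequence[GeneModel]
) -> list[ExpressionRecord]:
    from .annotation_io import XGF_CATEGORIES

    records = []
    for g in genes:
        if g.category == "HKG":
            mean_rpkm = config.hkg_rpkm_mean
        elif g.category in XGF_CATEGORIES:
            mean_rpkm = config.xgf_rpkm_mean
        else:
            mean_rpkm = config.other_rpkm_mean
        tlen = sum(e - s for s, e in g.exons)
        for tissue in ("testis", "ovary"):
            expected = mean_rpkm * (tlen / 1e3) * (config.library_size / 1e6)
            count = int(rng.poisson(expected))
            records.append(
                ExpressionRecord(
                    gene_id=g.gene_id, tissue=tissue,
                    read_count=min(count, config.library_size),
                    transcript_length=tlen, library_size=config.library_size,
                )
            )
    return records


def simulate_genome(config: SimConfig | None = None, seed: int | None = None) -> SimulatedGenome:
    """Simulate a multi-species annotation bundle under ``config``.

    ``seed`` overrides ``config.seed`` when given.  Identical configurations
    and seeds yield identical results (and identical files via
    :meth:`SimulatedGenome.write`).
    """
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = _build_family_pool(config, rng)

    species: dict[str, SpeciesData] = {}
    truth_rows = []
    for i in range(config.n_species):
        sp_id = f"species{i}"
        chroms, genes, table = _simulate_genes(config, rng, sp_id)
        fams = []
        lo, hi = config.shared_family_offset_range
        for fam in pool:
            if sp_id not in fam.species:
                continue
            if len(fam.species) > 1:
                offset = float(rng.uniform(lo, hi))
                seq = mutate_sequence(fam.archetype, offset, rng)
            else:
                seq = fam.archetype
            fams.append(
                SimpleNamespace(
                    family_id=fam.family_id, classification=fam.classification,
                    age=fam.age, sequence=seq,
                )
            )
        tes = _simulate_tes(config, rng, chroms, genes, fams)
        expression = _simulate_expression(config, rng, genes) if i == 0 else []
        consensi = [
            TEFamilyConsensus(family_id=f.family_id, species_id=sp_id, sequence=f.sequence)
            for f in fams
        ]
        species[sp_id] = SpeciesData(
            species_id=sp_id, chrom_specs=chroms, genes=genes, tes=tes,
            category_table=table, consensi=consensi, expression=expression,
        )
        truth_rows.append({"scope": sp_id, "key": "n_tes", "value": len(tes)})

    truth_rows.extend(
        [
            {"scope": "global", "key": "seed", "value": config.seed},
            {"scope": "global", "key": "te_rate_per_mb", "value": config.te_rate_per_mb},
            {"scope": "global", "key": "te_length_mean", "value": config.te_length_mean},
            {"scope": "global", "key": "hkg_vs_xgf_rpkm_fold",
             "value": config.hkg_rpkm_mean / config.xgf_rpkm_mean},
        ]
    )
    for cat, (cov, cnt) in sorted(config.enrichment.items()):
        truth_rows.append({"scope": cat, "key": "planted_coverage_mult", "value": cov})
        truth_rows.append({"scope": cat, "key": "planted_count_mult", "value": cnt})
    for fam in pool:
        truth_rows.append(
            {"scope": fam.family_id, "key": "n_species_sharing", "value": len(fam.species)}
        )
        truth_rows.append({"scope": fam.family_id, "key": "age", "value": fam.age})
    return SimulatedGenome(config=config, species=species, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# deterministic edge-case fixtures
# ---------------------------------------------------------------------------

def fixture_suite() -> dict[str, SimpleNamespace]:
    """Small hand-built genomes exercising edge paths.

    Deterministic by construction (no random draws): single-gene chromosome,
    abutting genes with colliding flanks, a TE spanning a locus-window
    boundary, a zero-SD gene-size category, and all-tie expression data.
    """
    chrom = ChromSpec("chr1", 100_000)
    single_gene = SimpleNamespace(
        chrom_specs=[chrom],
        genes=[GeneModel("g1", "chr1", "+", [(30_000, 40_000)], "CYP", "insecticide")],
        tes=[],
    )
    colliding = SimpleNamespace(
        chrom_specs=[chrom],
        genes=[
            GeneModel("gA", "chr1", "+", [(20_000, 30_000)]),
            GeneModel("gB", "chr1", "+", [(35_000, 45_000)]),
        ],
        tes=[],
    )
    boundary_te = SimpleNamespace(
        chrom_specs=[chrom],
        genes=[GeneModel("g1", "chr1", "+", [(30_000, 40_000)], "GST")],
        # window is (10000, 60000); one TE abuts the end (no overlap), one spans it
        tes=[
            TEInsertion("chr1", 60_000, 61_000, "famA", "DNA"),
            TEInsertion("chr1", 59_500, 60_500, "famB", "LINE"),
        ],
    )
    zero_sd = SimpleNamespace(
        chrom_specs=[chrom],
        genes=[
            GeneModel(f"g{i}", "chr1", "+", [(10_000 * (i + 1), 10_000 * (i + 1) + 2_000)], "UGT")
            for i in range(3)
        ],
        tes=[],
    )
    tied_expression = SimpleNamespace(
        records=[
            ExpressionRecord(f"g{i}", tissue, 100, 1_000, 1_000_000)
            for i in range(4)
            for tissue in ("testis", "ovary")
        ],
        categories={"g0": "CYP", "g1": "CYP", "g2": "HKG", "g3": "HKG"},
    )
    return {
        "single_gene": single_gene,
        "colliding_flanks": colliding,
        "boundary_te": boundary_te,
        "zero_sd_category": zero_sd,
        "tied_expression": tied_expression,
    }
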