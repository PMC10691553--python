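"""End-to-end orchestration: config validation, stage sequencing, and
deterministic TSV outputs.

``run_all`` reads per-species annotation inputs, defragments TE calls,
partitions chromosomes into compartments, profiles every gene locus, and
emits the analysis tables (compartment occupancy, compactness, species and
category enrichment, hotspots, repeat landscape, family sharing, expression
contrast) plus a run manifest carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    XGF_CATEGORIES,
    defragment,
    read_category_table,
    read_chrom_sizes,
    read_gene_gff,
    read_te_annotation,
)
from .compartments import (
    build_compartment_map,
    compactness_ratio,
    compartment_occupancy,
    profile_locus,
)
from .enrichment_stats import (
    call_hotspots,
    category_enrichment_table,
    locus_table,
    species_enrichment_table,
)
from .expression import germline_contrast_by_tissue, read_expression_tsv, rpkm_table
from .family_clustering import greedy_cluster, read_consensus_fasta, sharing_profile
from .te_divergence import build_landscape

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class SpeciesInputs:
    species_id: str
    genes_gff: Path
    te_annotation: Path
    chrom_sizes: Path
    categories: Path | None = None
    consensus_fasta: Path | None = None
    expression: Path | None = None


@dataclass
class PipelineConfig:
    species: list[SpeciesInputs]
    flank_size: int = 20_000
    max_gap: int = 200
    cluster_c: float = 0.8
    cluster_aS: float = 0.8
    coverage_threshold: int = 35_000
    count_threshold: int = 80
    alpha: float = 0.05
    fold_ndigits: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [
            SpeciesInputs(
                species_id=s["id"],
                genes_gff=Path(s["genes_gff"]),
                te_annotation=Path(s["te_annotation"]),
                chrom_sizes=Path(s["chrom_sizes"]),
                categories=Path(s["categories"]) if s.get("categories") else None,
                consensus_fasta=Path(s["consensus_fasta"]) if s.get("consensus_fasta") else None,
                expression=Path(s["expression"]) if s.get("expression") else None,
            )
            for s in raw.pop("species")
        ]
        return cls(species=species, **raw)

    def validate(self) -> None:
        if not self.species:
            raise PipelineError("config lists no species")
        for s in self.species:
            for label, p in (
                ("genes_gff", s.genes_gff), ("te_annotation", s.te_annotation),
                ("chrom_sizes", s.chrom_sizes), ("categories", s.categories),
                ("consensus_fasta", s.consensus_fasta), ("expression", s.expression),
            ):
                if p is not None and not Path(p).exists():
                    raise PipelineError(
                        f"missing input for species {s.species_id}: {label} path {p}"
                    )
        if not (0 < self.cluster_c <= 1 and 0 < self.cluster_aS <= 1):
            raise PipelineError("clustering thresholds must be in (0, 1]")
        if self.flank_size < 0 or self.max_gap < 0:
            raise PipelineError("flank_size and max_gap must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        d = {
            "flank_size": self.flank_size, "max_gap": self.max_gap,
            "cluster_c": self.cluster_c, "cluster_aS": self.cluster_aS,
            "coverage_threshold": self.coverage_threshold,
            "count_threshold": self.count_threshold,
            "alpha": self.alpha, "fold_ndigits": self.fold_ndigits, "seed": self.seed,
            "species": [
                {"id": s.species_id, "genes_gff": str(s.genes_gff),
                 "te_annotation": str(s.te_annotation), "chrom_sizes": str(s.chrom_sizes),
                 "categories": str(s.categories) if s.categories else None,
                 "consensus_fasta": str(s.consensus_fasta) if s.consensus_fasta else None,
                 "expression": str(s.expression) if s.expression else None}
                for s in self.species
            ],
        }
        return d

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write the report directory.

    Inputs are never mutated; all tables are sorted deterministically and
    the manifest records the package version, config hash and seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    occupancy_rows = []
    compact_rows = []
    tables = {}
    hotspot_rows = []
    landscape_rows = []
    all_consensi = []
    expression_rows = []

    for sp in config.species:
        load = _stage(f"load:{sp.species_id}")(_load_species)
        chroms, genes, tes = load(sp)
        tes = _stage(f"defragment:{sp.species_id}")(defragment)(tes, config.max_gap)

        cmaps = _stage(f"partition:{sp.species_id}")(
            lambda: [build_compartment_map(genes, c, config.flank_size) for c in chroms]
        )()
        occ = compartment_occupancy(cmaps, tes)
        occ.insert(0, "species", sp.species_id)
        occupancy_rows.append(occ)
        comp = compactness_ratio(cmaps)
        compact_rows.append(
            {"species": sp.species_id, "genic_bp": comp.genic_bp,
             "intergenic_bp": comp.intergenic_bp, "ratio": comp.ratio,
             "ratio_rounded": comp.ratio_rounded}
        )

        profiles = _stage(f"profile:{sp.species_id}")(profile_locus)(
            genes, tes, chroms, config.flank_size
        )
        tables[sp.species_id] = locus_table(genes, profiles, species=sp.species_id)

        for call in call_hotspots(
            genes, profiles, species=sp.species_id,
            coverage_threshold=config.coverage_threshold,
            count_threshold=config.count_threshold,
        ):
            hotspot_rows.append(vars(call))

        land = build_landscape(tes).to_frame()
        land.insert(0, "species", sp.species_id)
        landscape_rows.append(land)

        if sp.consensus_fasta is not None:
            all_consensi.extend(read_consensus_fasta(sp.consensus_fasta, sp.species_id))
        if sp.expression is not None:
            records = read_expression_tsv(sp.expression)
            cats = {g.gene_id: g.category for g in genes}
            rtab = rpkm_table(records, cats)
            contrast = germline_contrast_by_tissue(rtab, XGF_CATEGORIES)
            contrast.insert(0, "species", sp.species_id)
            expression_rows.append(contrast)

    _write_tsv(pd.concat(occupancy_rows, ignore_index=True),
               outdir / "compartment_occupancy.tsv")
    _write_tsv(pd.DataFrame(compact_rows), outdir / "compactness.tsv")

    enrich_sp, cross = _stage("enrichment")(species_enrichment_table)(tables)
    _write_tsv(enrich_sp, outdir / "enrichment_species.tsv")
    pooled = pd.concat(tables.values(), ignore_index=True)
    _write_tsv(_stage("enrichment-category")(category_enrichment_table)(pooled),
               outdir / "enrichment_category.tsv")

    hot = pd.DataFrame(hotspot_rows).sort_values(["species", "gene_id"])
    _write_tsv(hot, outdir / "hotspots.tsv")
    _write_tsv(pd.concat(landscape_rows, ignore_index=True), outdir / "landscape.tsv")

    if all_consensi:
        clusters = _stage("clustering")(greedy_cluster)(
            all_consensi, c=config.cluster_c, aS=config.cluster_aS
        )
        prof = sharing_profile(clusters, [s.species_id for s in config.species])
        _write_tsv(prof.reset_index(), outdir / "sharing.tsv")

    if expression_rows:
        _write_tsv(pd.concat(expression_rows, ignore_index=True),
                   outdir / "expression_contrast.tsv")

    manifest = {
        "telocus_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "config": config.to_dict(),
        "cross_species_tests": {
            metric: {"H": h, "p_value": p} for metric, (h, p) in cross.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _load_species(sp: SpeciesInputs):
    chroms = read_chrom_sizes(sp.chrom_sizes)
    cats = read_category_table(sp.categories) if sp.categories else {}
    genes = read_gene_gff(sp.genes_gff, cats, chroms)
    tes = read_te_annotation(sp.te_annotation, chroms)
    return chroms, genes, tes
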