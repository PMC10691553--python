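"""RPKM normalization and germline expression contrast.

RPKM (reads per kilobase of transcript per million mapped reads) puts read
counts from libraries of different depth on one scale:

    rpkm = read_count * 1e9 / (transcript_length * library_size)

The germline contrast compares focal-gene expression against housekeeping
genes in germline tissues (testis, ovary) with a two-sided rank-sum test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ExpressionRecord
from .enrichment_stats import fold_change, rank_sum_test

GERMLINE_TISSUES = ("testis", "ovary")


def rpkm(read_count: float, transcript_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length_bp < 1:
        raise ValueError(f"transcript_length must be >= 1, got {transcript_length_bp}")
    if library_size < 1:
        raise ValueError(f"library_size must be >= 1, got {library_size}")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count * 1e9 / (transcript_length_bp * library_size)


def rpkm_table(records: Sequence[ExpressionRecord],
               categories: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tidy table of per-gene, per-tissue RPKM values."""
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "rpkm": rpkm(r.read_count, r.transcript_length, r.library_size),
            "category": categories.get(r.gene_id, "other") if categories else "other",
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def germline_contrast(
    xgf_rpkm: Sequence[float], hkg_rpkm: Sequence[float]
) -> dict[str, float]:
    """Two-sided rank-sum contrast of focal-gene vs housekeeping RPKM.

    Returns W (Mann-Whitney U of the HKG sample, the larger-expression arm
    under the housekeeping hypothesis), the p-value, both means, and the
    HKG/XGF fold change.
    """
    x = np.asarray(xgf_rpkm, dtype=float)
    h = np.asarray(hkg_rpkm, dtype=float)
    if x.size == 0 or h.size == 0:
        raise ValueError("both expression sets must be non-empty")
    w, p = rank_sum_test(h, x)
    raw, rounded = fold_change(float(h.mean()), float(x.mean()))
    return {
        "W": w,
        "p_value": p,
        "mean_xgf": float(x.mean()),
        "mean_hkg": float(h.mean()),
        "fold_hkg_over_xgf_raw": raw,
        "fold_hkg_over_xgf": rounded,
        "n_xgf": int(x.size),
        "n_hkg": int(h.size),
    }


def germline_contrast_by_tissue(
    table: pd.DataFrame,
    focal_categories: Sequence[str],
    hkg_category: str = "HKG",
    tissues: Sequence[str] = GERMLINE_TISSUES,
) -> pd.DataFrame:
    """Germline contrast per tissue plus pooled across germline tissues.

    The pooled row averages each gene's RPKM across the germline tissues
    before testing.
    """
    rows = []
    germ = table[table["tissue"].isin(tissues)]
    for tissue in tissues:
        sub = germ[germ["tissue"] == tissue]
        rows.append(_contrast_row(sub, focal_categories, hkg_category, tissue))
    pooled = (
        germ.groupby(["gene_id", "category"], as_index=False)["rpkm"].mean()
    )
    rows.append(_contrast_row(pooled, focal_categories, hkg_category, "germline_pooled"))
    return pd.DataFrame(rows)


def _contrast_row(sub: pd.DataFrame, focal_categories, hkg_category, label) -> dict:
    x = sub.loc[sub["category"].isin(focal_categories), "rpkm"].to_numpy()
    h = sub.loc[sub["category"] == hkg_category, "rpkm"].to_numpy()
    res = germline_contrast(x, h)
    res["tissue"] = label
    return res


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene_id, tissue, read_count,
    transcript_length, library_size (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "tissue", "read_count", "transcript_length", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExpressionRecord(
            gene_id=str(r.gene_id), tissue=str(r.tissue), read_count=int(r.read_count),
            transcript_length=int(r.transcript_length), library_size=int(r.library_size),
        )
        for r in df.itertuples()
    ]


def write_expression_tsv(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    lines = ["gene_id\ttissue\tread_count\ttranscript_length\tlibrary_size"]
    for r in sorted(records, key=lambda r: (r.gene_id, r.tissue)):
        lines.append(
            f"{r.gene_id}\t{r.tissue}\t{r.read_count}\t{r.transcript_length}\t{r.library_size}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
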