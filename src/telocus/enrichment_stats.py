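"""Enrichment statistics for TE occupancy at focal gene sets.

Fold-change enrichment of focal gene sets over background genes, rank-based
tests (Wilcoxon rank-sum, Kruskal-Wallis), per-species enrichment tables,
hotspot calling with TE-excised gene-size Z-scores, fragment-length
summaries, genome-size/TE-content regression, and the phylogenetic
heritability ratio Vp/(Vp + Vs) with its highest-posterior-density interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, XGF_CATEGORIES
from .compartments import LocusTEProfile

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 35_000  # bp of TE sequence in the locus window
DEFAULT_COUNT_THRESHOLD = 80         # TE insertions in the locus window


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold-change plus rank-sum test for one focal-vs-background contrast."""

    focal_set: str
    background: str
    metric: str  # "coverage_bp" or "count"
    focal_mean: float
    background_mean: float
    fold_change_raw: float
    fold_change: float  # display-rounded (round-half-even)
    test_statistic: float
    p_value: float
    n_focal: int
    n_background: int


@dataclass
class HotspotCall:
    """Per-gene hotspot call with raw and TE-excised gene-size Z-scores."""

    gene_id: str
    species: str
    category: str
    coverage_bp: int
    count: int
    gene_size: int
    gene_size_z: float          # nan when category has < 3 members or SD == 0
    gene_size_z_te_removed: float
    is_hotspot: bool


@dataclass(frozen=True)
class PosteriorSamples:
    """Paired posterior samples of phylogenetic (Vp) and species-specific
    (Vs) variance components."""

    v_p: np.ndarray
    v_s: np.ndarray

    def __post_init__(self) -> None:
        vp = np.asarray(self.v_p, dtype=float)
        vs = np.asarray(self.v_s, dtype=float)
        if vp.shape != vs.shape or vp.ndim != 1 or vp.size < 2:
            raise ValueError("v_p and v_s must be equal-length 1-D arrays with >= 2 samples")
        if (vp < 0).any() or (vs < 0).any():
            raise ValueError("variance samples must be non-negative")
        object.__setattr__(self, "v_p", vp)
        object.__setattr__(self, "v_s", vs)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def fold_change(
    focal_mean: float, background_mean: float, ndigits: int = 1
) -> tuple[float, float]:
    """Enrichment multiple focal/background.

    Returns ``(raw, rounded)``; rounding is round-half-even to ``ndigits``
    (the raw ratio is always reported alongside the display value).  A zero
    background yields ``(nan, nan)``.
    """
    if background_mean == 0:
        return (math.nan, math.nan)
    raw = focal_mean / background_mean
    return raw, round(raw, ndigits)


def rank_sum_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    The statistic is the Mann-Whitney U of the first sample (the W reported
    by R's wilcox.test).  P-values are exact (full enumeration) when
    n_a + n_b <= 12 and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis one-way rank analysis with tie correction.

    All-identical data degenerate to (H=0, p=1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# locus tables and per-species enrichment
# ---------------------------------------------------------------------------

def locus_table(
    genes: Sequence[GeneModel],
    profiles: Sequence[LocusTEProfile],
    species: str = "",
) -> pd.DataFrame:
    """Join gene metadata and locus profiles into one tidy table."""
    by_id = {p.gene_id: p for p in profiles}
    rows = []
    for g in genes:
        p = by_id[g.gene_id]
        rows.append(
            {
                "species": species,
                "gene_id": g.gene_id,
                "category": g.category,
                "cyp_function": g.cyp_function,
                "gene_size": g.length,
                "coverage_bp": p.coverage_bp,
                "count": p.count,
                "genic_te_bp": p.genic_te_bp,
            }
        )
    return pd.DataFrame(rows)


def _contrast(
    df: pd.DataFrame,
    focal_mask: np.ndarray,
    background_mask: np.ndarray,
    metric: str,
    focal_label: str,
    background_label: str,
) -> EnrichmentResult:
    focal = df.loc[focal_mask, metric].to_numpy(dtype=float)
    background = df.loc[background_mask, metric].to_numpy(dtype=float)
    raw, rounded = fold_change(float(focal.mean()), float(background.mean()))
    w, p = rank_sum_test(focal, background)
    return EnrichmentResult(
        focal_set=focal_label,
        background=background_label,
        metric=metric,
        focal_mean=float(focal.mean()),
        background_mean=float(background.mean()),
        fold_change_raw=raw,
        fold_change=rounded,
        test_statistic=w,
        p_value=p,
        n_focal=int(focal.size),
        n_background=int(background.size),
    )


def species_enrichment_table(
    tables: Mapping[str, pd.DataFrame],
    focal_categories: Sequence[str] = XGF_CATEGORIES,
    metrics: Sequence[str] = ("coverage_bp", "count"),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-species fold change and rank-sum test of focal genes vs the rest.

    ``tables`` maps species id to a :func:`locus_table` frame.  The second
    return value is a cross-species rank-based one-way analysis (Kruskal-
    Wallis over per-focal-gene metric values grouped by species), one entry
    per metric.  Species with no focal genes are skipped with a warning.
    """
    rows = []
    per_species_focal: dict[str, dict[str, np.ndarray]] = {m: {} for m in metrics}
    for sp, df in sorted(tables.items()):
        focal_mask = df["category"].isin(focal_categories).to_numpy()
        background_mask = ~focal_mask
        if focal_mask.sum() == 0 or background_mask.sum() == 0:
            logger.warning("species %s has no focal or no background genes; skipped", sp)
            continue
        for metric in metrics:
            r = _contrast(df, focal_mask, background_mask, metric,
                          "+".join(focal_categories), "background")
            rows.append(
                {"species": sp, "metric": metric, "focal_mean": r.focal_mean,
                 "background_mean": r.background_mean, "fold_change_raw": r.fold_change_raw,
                 "fold_change": r.fold_change, "W": r.test_statistic, "p_value": r.p_value,
                 "n_focal": r.n_focal, "n_background": r.n_background}
            )
            per_species_focal[metric][sp] = df.loc[focal_mask, metric].to_numpy(dtype=float)
    cross: dict[str, tuple[float, float]] = {}
    for metric in metrics:
        groups = list(per_species_focal[metric].values())
        if len(groups) >= 2:
            cross[metric] = kruskal_wallis(groups)
    return pd.DataFrame(rows), cross


def category_enrichment_table(
    df: pd.DataFrame,
    categories: Sequence[str] = XGF_CATEGORIES,
    metrics: Sequence[str] = ("coverage_bp", "count"),
) -> pd.DataFrame:
    """Per-category enrichment against non-focal background genes."""
    background_mask = ~df["category"].isin(list(categories) + ["HKG"]).to_numpy()
    rows = []
    for cat in categories:
        focal_mask = (df["category"] == cat).to_numpy()
        if focal_mask.sum() == 0:
            continue
        for metric in metrics:
            r = _contrast(df, focal_mask, background_mask, metric, cat, "background")
            rows.append(
                {"category": cat, "metric": metric, "focal_mean": r.focal_mean,
                 "background_mean": r.background_mean,
                 "fold_change_raw": r.fold_change_raw, "fold_change": r.fold_change,
                 "W": r.test_statistic, "p_value": r.p_value,
                 "n_focal": r.n_focal, "n_background": r.n_background}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def _zscores(values: np.ndarray) -> np.ndarray:
    """Population-SD Z-scores; nan when < 3 members or SD == 0."""
    if values.size < 3:
        return np.full(values.size, np.nan)
    sd = values.std()  # population SD
    if sd == 0:
        return np.full(values.size, np.nan)
    return (values - values.mean()) / sd


def call_hotspots(
    genes: Sequence[GeneModel],
    profiles: Sequence[LocusTEProfile],
    species: str = "",
    coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> list[HotspotCall]:
    """Call TE hotspots and compute gene-size Z-scores within category.

    A gene is a hotspot when its window holds more than
    ``coverage_threshold`` bp of TE sequence AND more than
    ``count_threshold`` insertions.  Z-scores of gene length are computed
    within each gene category for this species, using the population SD; the
    TE-excised variant subtracts TE bp overlapping the gene body before
    standardizing, isolating size inflation attributable to TEs.
    Output order follows sorted gene_id, independent of input order.
    """
    by_id = {p.gene_id: p for p in profiles}
    ordered = sorted(genes, key=lambda g: g.gene_id)
    sizes = np.array([g.length for g in ordered], dtype=float)
    sizes_te_removed = np.array(
        [g.length - by_id[g.gene_id].genic_te_bp for g in ordered], dtype=float
    )
    categories = np.array([g.category for g in ordered])
    z = np.full(len(ordered), np.nan)
    z_removed = np.full(len(ordered), np.nan)
    for cat in np.unique(categories):
        idx = np.flatnonzero(categories == cat)
        z[idx] = _zscores(sizes[idx])
        z_removed[idx] = _zscores(sizes_te_removed[idx])
    calls = []
    for i, g in enumerate(ordered):
        p = by_id[g.gene_id]
        calls.append(
            HotspotCall(
                gene_id=g.gene_id,
                species=species,
                category=g.category,
                coverage_bp=p.coverage_bp,
                count=p.count,
                gene_size=g.length,
                gene_size_z=float(z[i]),
                gene_size_z_te_removed=float(z_removed[i]),
                is_hotspot=bool(p.coverage_bp > coverage_threshold
                                and p.count > count_threshold),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# fragment lengths, regression, heritability, CYP contrasts
# ---------------------------------------------------------------------------

def fragment_length_summary(
    lengths: Sequence[float], cutoff: int = 1000, bin_width: int = 250
) -> tuple[float, float, pd.DataFrame]:
    """Mean TE fragment length, fraction below ``cutoff``, and a histogram
    with fixed ``bin_width`` bp bins."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one TE length is required")
    mean = float(arr.mean())
    frac_below = float((arr < cutoff).mean())
    n_bins = int(arr.max() // bin_width) + 1
    counts, edges = np.histogram(arr, bins=np.arange(0, (n_bins + 1) * bin_width, bin_width))
    hist = pd.DataFrame({"bin_low": edges[:-1].astype(int), "count": counts})
    return mean, frac_below, hist


def te_genome_regression(
    genome_size: Sequence[float], te_content_pct: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of TE content on genome size across species.

    Returns ``(slope, F, p, R2)``; F is the one-slope F statistic (t^2).
    """
    x = np.asarray(genome_size, dtype=float)
    y = np.asarray(te_content_pct, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 species")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    if res.stderr == 0:
        f = math.inf
    else:
        f = (res.slope / res.stderr) ** 2
    return float(res.slope), float(f), float(res.pvalue), float(res.rvalue ** 2)


def heritability(samples: PosteriorSamples, cred: float = 0.95
                 ) -> tuple[float, tuple[float, float]]:
    """Phylogenetic heritability Vp/(Vp + Vs): posterior mean and HPD.

    Samples with Vp + Vs == 0 are dropped with a warning.  The HPD is the
    shortest interval over the sorted per-sample ratios containing a
    ``cred`` fraction of them.
    """
    total = samples.v_p + samples.v_s
    keep = total > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} sample(s) with Vp + Vs == 0")
    vp, tot = samples.v_p[keep], total[keep]
    if vp.size < 2:
        raise ValueError("fewer than 2 usable samples")
    r = np.sort(vp / tot)
    n = r.size
    m = max(1, int(math.ceil(cred * n)))
    if m >= n:
        return float(r.mean()), (float(r[0]), float(r[-1]))
    widths = r[m - 1 + np.arange(n - m + 1)] - r[: n - m + 1]
    i = int(np.argmin(widths))
    return float(r.mean()), (float(r[i]), float(r[i + m - 1]))


_RESISTANCE_LINKED = ("xenobiotic", "insecticide", "natural")


def cyp_function_contrast(
    df: pd.DataFrame, metric: str = "coverage_bp", min_per_arm: int = 2
) -> dict[str, EnrichmentResult]:
    """Contrast TE occupancy of CYP genes by functional label.

    Two contrasts on CYP genes of one species: resistance-linked (labels
    xenobiotic/insecticide/natural) vs other function, and insecticide vs
    natural resistance.  A contrast with fewer than ``min_per_arm`` genes in
    either arm is skipped with a warning.
    """
    cyp = df[df["category"] == "CYP"]
    results: dict[str, EnrichmentResult] = {}
    contrasts = {
        "xenobiotic_vs_other": (
            cyp["cyp_function"].isin(_RESISTANCE_LINKED).to_numpy(),
            (cyp["cyp_function"] == "other").to_numpy(),
            "CYP:resistance-linked", "CYP:other-function",
        ),
        "insecticide_vs_natural": (
            (cyp["cyp_function"] == "insecticide").to_numpy(),
            (cyp["cyp_function"] == "natural").to_numpy(),
            "CYP:insecticide", "CYP:natural",
        ),
    }
    for name, (fmask, bmask, flab, blab) in contrasts.items():
        if fmask.sum() < min_per_arm or bmask.sum() < min_per_arm:
            logger.warning("contrast %s skipped: < %d genes per arm", name, min_per_arm)
            continue
        results[name] = _contrast(cyp, fmask, bmask, metric, flab, blab)
    return results


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional switch; raw p-values
    are reported by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
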