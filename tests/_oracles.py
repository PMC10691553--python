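"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-base scans, all-pairs loops, full
dynamic-programming matrices) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import numpy as np

LABELS = ("exon", "intron", "flank5", "flank3", "intergenic")


def per_base_labels(genes, length: int, flank_size: int) -> list[str]:
    """O(L) per-base compartment labeling.

    Precedence exon > intron > flank > intergenic; flank bases go to the
    nearest gene (distance to the closest gene-body base), ties prefer a
    5'-side flank and then the left gene.
    """
    out = []
    for b in range(length):
        label = None
        for g in genes:
            for s, e in g.exons:
                if s <= b < e:
                    label = "exon"
                    break
            if label:
                break
        if label is None:
            for g in genes:
                if g.start <= b < g.end:
                    label = "intron"
                    break
        if label is None:
            best = None  # (distance, flank5-first, gene_id, label)
            for g in genes:
                if b < g.start:
                    dist = g.start - b
                    side = "left"
                else:
                    dist = b - g.end + 1
                    side = "right"
                if dist > flank_size:
                    continue
                if side == "left":
                    lab = "flank5" if g.strand == "+" else "flank3"
                else:
                    lab = "flank3" if g.strand == "+" else "flank5"
                key = (dist, lab != "flank5", g.gene_id)
                if best is None or key < best[0]:
                    best = (key, lab)
            label = best[1] if best else "intergenic"
        out.append(label)
    return out


def per_base_occupancy(labels: list[str], tes) -> dict[str, int]:
    """Per-base TE bp per compartment label (union over TEs)."""
    covered = np.zeros(len(labels), dtype=bool)
    for t in tes:
        covered[t.start:t.end] = True
    totals = {lab: 0 for lab in LABELS}
    for b, lab in enumerate(labels):
        if covered[b]:
            totals[lab] += 1
    return totals


def all_pairs_profile(gene, tes, length: int, flank_size: int):
    """All-pairs locus profile for one gene: (coverage, count, genic bp)."""
    ws, we = max(0, gene.start - flank_size), min(length, gene.end + flank_size)
    covered = np.zeros(length, dtype=bool)
    genic = np.zeros(length, dtype=bool)
    count = 0
    for t in tes:
        lo, hi = max(t.start, ws), min(t.end, we)
        if lo < hi:
            count += 1
            covered[lo:hi] = True
        glo, ghi = max(t.start, gene.start), min(t.end, gene.end)
        if glo < ghi:
            genic[glo:ghi] = True
    return int(covered.sum()), count, int(genic.sum())


def naive_defragment(tes, max_gap: int):
    """Left-to-right transitive merge per (chrom, family), strand-compatible,
    gap <= max_gap; returns list of (chrom, family, strand, start, end)."""
    groups: dict[tuple[str, str], list] = {}
    for t in tes:
        groups.setdefault((t.chrom, t.family_id), []).append(t)
    merged = []
    for (chrom, fam), ts in groups.items():
        ts = sorted(ts, key=lambda t: (t.start, t.end, t.strand))
        cur = [chrom, fam, ts[0].strand, ts[0].start, ts[0].end]
        for t in ts[1:]:
            compatible = cur[2] == "." or t.strand == "." or cur[2] == t.strand
            if t.start - cur[4] <= max_gap and compatible:
                cur[4] = max(cur[4], t.end)
                if cur[2] == ".":
                    cur[2] = t.strand
            else:
                merged.append(tuple(cur))
                cur = [chrom, fam, t.strand, t.start, t.end]
        merged.append(tuple(cur))
    return sorted(merged)


def count_columns(consensus: str, copy: str):
    """Per-column transition/transversion count, no CpG weighting."""
    purines = {"A", "G"}
    bases = set("ACGT")
    ts = tv = sites = 0
    for a, b in zip(consensus.upper(), copy.upper()):
        if a not in bases or b not in bases:
            continue
        sites += 1
        if a == b:
            continue
        if (a in purines) == (b in purines):
            ts += 1
        else:
            tv += 1
    return ts, tv, sites


def gotoh_local_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Affine-gap Smith-Waterman best local score (full DP matrix).

    gap_open is the cost of a gap of length 1; each extension adds
    gap_extend (matching the PairwiseAligner open/extend convention).
    """
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def permutation_ranksum_p(a, b, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for the rank-sum statistic of sample a
    (midranks), estimated from random permutations."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[:na].sum()
    mu = na * (pooled.size + 1) / 2.0
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[:na].sum() - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / n_perm


def naive_greedy_cluster(consensi, c: float, aS: float, identity_fn):
    """Re-run of the greedy rule with a naive all-pairs loop: sequences in
    length-descending order join the best qualifying representative
    (highest identity, then longest representative, then id order)."""
    order = sorted(consensi, key=lambda x: (-len(x.sequence), x.family_id, x.species_id))
    clusters: list[list] = []
    reps: list = []
    for x in order:
        best = None
        for idx, rep in enumerate(reps):
            identity, coverage = identity_fn(rep.sequence, x.sequence)
            if identity >= c and coverage >= aS:
                key = (-identity, -len(rep.sequence), rep.family_id, rep.species_id)
                if best is None or key < best[0]:
                    best = (key, idx)
        if best is None:
            reps.append(x)
            clusters.append([x.key])
        else:
            clusters[best[1]].append(x.key)
    return [sorted(members) for members in clusters]
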