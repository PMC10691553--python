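"""Kimura two-parameter divergence of TE copies from consensus and repeat
landscapes.

The Kimura two-parameter model separates transitions (fraction ``p``) from
transversions (``q``); the distance is

    d = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

CpG adjustment follows the standard repeat-divergence convention for
hypermutable CpG sites: a transition observed at a consensus CpG dinucleotide
is down-weighted to 1/10 of a substitution, and two transitions within one
CpG site count as a single (weighted) transition.  Per-copy divergences are
binned into a repeat landscape (bp of TE sequence per divergence bin and
classification), where low divergence is a proxy for recent TE activity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import TEInsertion, TE_CLASSIFICATIONS

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = {"A", "C", "G", "T"}

#: Weight applied to a transition at a consensus CpG site.
CPG_TRANSITION_WEIGHT = 0.1


class KimuraSaturationError(ValueError):
    """The (p, q) pair lies outside the domain of the Kimura 2P distance."""


def kimura2p(p: float, q: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions.

    Requires ``1 - 2p - q > 0`` and ``1 - 2q > 0``; outside that domain the
    distance is undefined (saturated) and :class:`KimuraSaturationError` is
    raised.
    """
    if p < 0 or q < 0:
        raise ValueError(f"p and q must be non-negative, got p={p}, q={q}")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise KimuraSaturationError(
            f"distance undefined for p={p}, q={q} (1-2p-q={w1:.4g}, 1-2q={w2:.4g})"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment of a TE copy against its family consensus.

    Both strings have equal length over the alphabet {A, C, G, T, -, N}.
    """

    consensus_seq: str
    copy_seq: str

    def __post_init__(self) -> None:
        if len(self.consensus_seq) != len(self.copy_seq):
            raise ValueError("aligned sequences must have equal length")
        if not self.consensus_seq:
            raise ValueError("empty alignment")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def count_substitutions_cpg(aln: PairwiseAlignment) -> tuple[float, float, int]:
    """Count CpG-weighted transition and transversion fractions.

    Only ungapped, non-N columns are counted as sites.  At consensus CpG
    dinucleotides (adjacent C,G in consensus coordinates) a transition is
    weighted ``1/10``, and two transitions inside one CpG site count once.
    Returns ``(p, q, sites)``.
    """
    cons = aln.consensus_seq.upper()
    copy = aln.copy_seq.upper()
    n = len(cons)
    valid = [
        i for i in range(n)
        if cons[i] in _BASES and copy[i] in _BASES
    ]
    if not valid:
        raise ValueError("alignment has no ungapped, unambiguous columns")

    # consensus CpG pairs: C followed by G in consensus coordinates (skipping
    # consensus gap columns)
    cons_positions = [i for i in range(n) if cons[i] != "-"]
    cpg_pairs: list[tuple[int, int]] = []
    for a, b in zip(cons_positions, cons_positions[1:]):
        if cons[a] == "C" and cons[b] == "G":
            cpg_pairs.append((a, b))
    in_cpg = {i: pair for pair in cpg_pairs for i in pair}

    transitions = 0.0
    transversions = 0.0
    counted_cpg_pairs: set[tuple[int, int]] = set()
    for i in valid:
        a, b = cons[i], copy[i]
        if a == b:
            continue
        if _is_transition(a, b):
            pair = in_cpg.get(i)
            if pair is not None:
                if pair in counted_cpg_pairs:
                    continue  # second transition in the same CpG: counted once
                counted_cpg_pairs.add(pair)
                transitions += CPG_TRANSITION_WEIGHT
            else:
                transitions += 1.0
        else:
            transversions += 1.0
    sites = len(valid)
    return transitions / sites, transversions / sites, sites


def divergence_from_alignment(aln: PairwiseAlignment) -> float:
    """CpG-adjusted Kimura 2P distance of a copy from its consensus."""
    p, q, _sites = count_substitutions_cpg(aln)
    return kimura2p(p, q)


# ---------------------------------------------------------------------------
# repeat landscapes
# ---------------------------------------------------------------------------

@dataclass
class RepeatLandscape:
    """bp of TE sequence per divergence bin (percent scale) and classification."""

    bin_width: float
    max_pct: float
    bp: "np.ndarray"  # shape (n_bins, n_classes)
    classifications: tuple[str, ...]

    @property
    def n_bins(self) -> int:
        return self.bp.shape[0]

    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, self.max_pct + self.bin_width, self.bin_width)

    def total_bp(self) -> float:
        return float(self.bp.sum())

    def to_frame(self):
        import pandas as pd

        rows = []
        for b in range(self.n_bins):
            for c, cls in enumerate(self.classifications):
                rows.append(
                    {"bin_low_pct": b * self.bin_width, "classification": cls,
                     "bp": float(self.bp[b, c])}
                )
        return pd.DataFrame(rows)


def build_landscape(
    tes: Iterable[TEInsertion],
    classifications: Sequence[str] = TE_CLASSIFICATIONS,
    bin_width: float = 1.0,
    max_pct: float = 50.0,
) -> RepeatLandscape:
    """Accumulate each copy's bp into the bin ``floor(divergence * 100 /
    bin_width)`` of its classification.

    Copies without a divergence are skipped; divergences above ``max_pct``
    clamp into the last bin with a warning.
    """
    n_bins = int(round(max_pct / bin_width))
    cls_index = {c: i for i, c in enumerate(classifications)}
    bp = np.zeros((n_bins, len(classifications)))
    clamped = 0
    for t in tes:
        if t.divergence is None:
            continue
        b = int(math.floor(t.divergence * 100.0 / bin_width))
        if b >= n_bins:
            b = n_bins - 1
            clamped += 1
        bp[b, cls_index[t.classification]] += t.length
    if clamped:
        warnings.warn(f"{clamped} TE(s) above {max_pct}% divergence clamped to last bin")
    return RepeatLandscape(bin_width, max_pct, bp, tuple(classifications))
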