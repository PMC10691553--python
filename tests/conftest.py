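import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from telocus.annotation_io import ChromSpec, GeneModel, TEInsertion
from telocus.synthetic_data import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_small_genome(rng, max_len=8_000, max_genes=3, max_tes=20, flank=None):
    """A random miniature genome for brute-force oracle comparisons."""
    L = int(rng.integers(2_000, max_len))
    flank = int(rng.integers(300, 1_500)) if flank is None else flank
    n_genes = int(rng.integers(0, max_genes + 1))
    genes = []
    cursor = 0
    for i in range(n_genes):
        gap = int(rng.integers(50, 800))
        start = cursor + gap
        if start + 300 >= L:
            break
        n_ex = int(rng.integers(1, 4))
        exons = []
        p = start
        for j in range(n_ex):
            el = int(rng.integers(30, 200))
            exons.append((p, min(p + el, L)))
            p += el + int(rng.integers(20, 150))
            if p >= L:
                break
        exons = [(s, e) for s, e in exons if s < e]
        if not exons:
            break
        genes.append(
            GeneModel(
                gene_id=f"g{i}",
                chrom="chr1",
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                category=str(rng.choice(["CYP", "other", "HKG"])),
            )
        )
        cursor = genes[-1].end
    tes = []
    n_tes = int(rng.integers(0, max_tes + 1))
    for i in range(n_tes):
        s = int(rng.integers(0, L - 1))
        e = min(L, s + int(rng.integers(1, 600)))
        tes.append(
            TEInsertion(
                chrom="chr1", start=s, end=e, family_id=f"fam{int(rng.integers(0, 4))}",
                classification=str(rng.choice(["DNA", "LINE", "LTR"])),
                strand=str(rng.choice(["+", "-", "."])),
            )
        )
    tes.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_id))
    return ChromSpec("chr1", L), genes, tes, flank
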