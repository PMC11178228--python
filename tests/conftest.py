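from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicescreen.annotation import GeneModel, IntronRecord
from splicescreen.simulate import GenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A small deterministic genome shared across read-only tests."""
    spec = GenomeSpec(n_genes=60)
    return simulate_genome(spec, seed=11)


@pytest.fixture(scope="session")
def three_intron_gene():
    """One plus-strand gene with three consensus (degeneracy 0) introns."""
    spec = GenomeSpec(
        n_genes=1,
        frac_intron_genes=1.0,
        intron_count_probs=np.array([0.0, 0.0, 1.0]),
        degeneracy=0.0,
    )
    genome, genes = simulate_genome(spec, seed=5)
    return genome, genes[0]


def make_gene(gene_id: str, n_introns: int = 0, chrom: str = "chr1") -> GeneModel:
    """Lightweight gene scaffold for tests that ignore sequence."""
    introns = [
        IntronRecord(gene_id, k + 1, chrom, 100 * (k + 1), 100 * (k + 1) + 50, "+")
        for k in range(n_introns)
    ]
    start = 1
    end = max((i.end for i in introns), default=50) + 50
    return GeneModel(gene_id, chrom, start, end, "+", [(start, end)], introns)


@pytest.fixture
def toy_ratio_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": ["mut"] * 3 + ["ref"] * 3,
            "ratio": [1.0, 1.1, 0.9, 2.0, 2.1, 1.9],
        }
    )
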