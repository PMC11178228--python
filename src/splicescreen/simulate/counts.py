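"""Read-count emission on top of the ground truth.

Junction evidence is emitted per intron boundary: the number of reads
observing a boundary is Poisson with mean ``depth * rate`` and each such
read is spliced with probability equal to the true splicing efficiency
(binomial thinning).  Gene-level counts are negative binomial with mean
proportional to ``rate * fold_change``; ``dispersion`` is the NB size
parameter (variance = mu + mu^2 / dispersion), so large dispersion
approaches Poisson and ``dispersion=inf`` is exactly Poisson.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .._seeds import child_rng
from .defects import TruthTable

__all__ = ["simulate_junction_counts", "simulate_gene_counts"]


def simulate_junction_counts(
    truth: TruthTable,
    rates: pd.DataFrame,
    depth: float,
    seed: int,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Emit per-intron junction counts for every genotype in ``truth``.

    Returns one row per (genotype, intron, replicate) with columns
    ``spliced5, unspliced5, spliced3, unspliced3``.  Replicates use
    distinct sub-seeds so adding replicates never perturbs earlier draws.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rate_map = dict(zip(rates["gene_id"], rates["rate"]))

    frames = []
    for genotype, sub in truth.introns.groupby("genotype", sort=True):
        gene_rates = sub["gene_id"].map(rate_map).to_numpy(float)
        true_se = sub["true_se"].to_numpy(float)
        lam = depth * gene_rates
        for rep in range(1, n_reps + 1):
            rng = child_rng(seed, "junctions", str(genotype), rep)
            n5 = rng.poisson(lam)
            n3 = rng.poisson(lam)
            spliced5 = rng.binomial(n5, true_se)
            spliced3 = rng.binomial(n3, true_se)
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": genotype,
                        "replicate": rep,
                        "intron_id": sub["intron_id"].to_numpy(),
                        "gene_id": sub["gene_id"].to_numpy(),
                        "intron_index": sub["intron_index"].to_numpy(),
                        "spliced5": spliced5,
                        "unspliced5": n5 - spliced5,
                        "spliced3": spliced3,
                        "unspliced3": n3 - spliced3,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_gene_counts(
    rates: pd.DataFrame,
    de_config: dict[str, float] | None,
    dispersion: float,
    n_reps: int,
    seed: int,
    depth_factor: float = 10.0,
    groups: tuple[str, str] = ("WT", "mut"),
) -> pd.DataFrame:
    """Raw count matrix (genes x samples) for a two-group comparison.

    ``de_config`` maps gene_id -> fold change applied in the second
    group; unlisted genes have fold change 1.  Column names are
    ``{group}_{rep}``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (biological duplicates at minimum)")
    de_config = de_config or {}
    gene_ids = rates["gene_id"].to_numpy()
    base_mu = rates["rate"].to_numpy(float) * depth_factor
    fc = np.array([de_config.get(g, 1.0) for g in gene_ids], dtype=float)

    if len(gene_ids) == 0:
        return pd.DataFrame(index=pd.Index([], name="gene_id"))

    cols: dict[str, np.ndarray] = {}
    for group, mu in ((groups[0], base_mu), (groups[1], base_mu * fc)):
        for rep in range(1, n_reps + 1):
            rng = child_rng(seed, "gene_counts", group, rep)
            if math.isinf(dispersion):
                counts = rng.poisson(mu)
            else:
                p = dispersion / (dispersion + mu)
                counts = rng.negative_binomial(dispersion, p)
            cols[f"{group}_{rep}"] = counts
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
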