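"""Co-splicing profiles, expression association, cumulative splicing.

These analyses probe the link between transcription and splicing:

* co-splicing profiles condition on one *anchor* intron of a
  multi-intron gene being strongly affected (mutant/WT SE ratio below a
  threshold, default 0.5) and report the positional mean SE of all
  introns of the passing genes — if defects are gene-level, non-anchor
  introns drop together with the anchor;
* expression association compares the host-gene FPKM of the k worst
  and k best spliced introns (t-test on log FPKM);
* the cumulative mature fraction is the product of a gene's per-intron
  efficiencies under an independent-splicing model — e.g. the four
  mmi1-style efficiencies 0.74, 0.71, 0.95, 0.85 multiply to ~0.424.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSpliceProfile",
    "CosplicingProfile",
    "build_gene_profiles",
    "cosplicing_profile",
    "expression_association",
    "cumulative_mature_fraction",
    "percent_splicing",
    "percent_retention",
]


@dataclass
class GeneSpliceProfile:
    gene_id: str
    se_wt: np.ndarray  # positionally ordered per-intron SE
    se_mut: np.ndarray
    fpkm: float

    @property
    def n_introns(self) -> int:
        return len(self.se_wt)


def build_gene_profiles(
    se_table: pd.DataFrame, fpkm: pd.DataFrame
) -> list[GeneSpliceProfile]:
    """Assemble per-gene positional SE profiles from a long SE table.

    ``se_table`` needs columns ``gene_id, intron_index, genotype, se``
    with genotypes ``WT`` and exactly one mutant; ``fpkm`` needs
    ``gene_id, fpkm``.  Genes with any NA intron in either genotype are
    dropped.
    """
    fpkm_map = dict(zip(fpkm["gene_id"], fpkm["fpkm"]))
    genotypes = sorted(se_table["genotype"].unique())
    muts = [g for g in genotypes if g != "WT"]
    if "WT" not in genotypes or len(muts) != 1:
        raise ValueError(f"need genotypes WT plus one mutant, got {genotypes}")
    wide = se_table.pivot_table(
        index=["gene_id", "intron_index"], columns="genotype", values="se"
    ).sort_index()
    profiles = []
    for gene_id, sub in wide.groupby(level="gene_id"):
        wt = sub["WT"].to_numpy(float)
        mut = sub[muts[0]].to_numpy(float)
        if np.isnan(wt).any() or np.isnan(mut).any():
            continue
        if gene_id not in fpkm_map:
            continue
        profiles.append(GeneSpliceProfile(gene_id, wt, mut, float(fpkm_map[gene_id])))
    return profiles


@dataclass
class CosplicingProfile:
    anchor_index: int  # 1-based
    comparator: str  # "lt" or "gt"
    threshold: float
    gene_ids: list[str]
    mean_se_wt: np.ndarray | None  # per position; None when no gene passes
    mean_se_mut: np.ndarray | None
    sd_se_wt: np.ndarray | None
    sd_se_mut: np.ndarray | None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def cosplicing_profile(
    profiles: Sequence[GeneSpliceProfile],
    n_introns: int = 3,
    anchor: int = 1,
    threshold: float = 0.5,
    comparator: str = "lt",
) -> CosplicingProfile:
    """Positional mean SE conditioned on the anchor intron's defect.

    A gene passes when ``se_mut[anchor] / se_wt[anchor] < threshold``
    (``comparator="lt"``; the ``"gt"`` variant with threshold 0.9 is the
    unaffected-anchor control).  Only genes with exactly ``n_introns``
    introns quantified in both genotypes are considered.  Zero passing
    genes yields an explicitly empty profile, not an error.
    """
    if comparator not in ("lt", "gt"):
        raise ValueError("comparator must be 'lt' or 'gt'")
    if not 1 <= anchor <= n_introns:
        raise ValueError("anchor must be within 1..n_introns")
    passing = []
    for prof in profiles:
        if prof.n_introns != n_introns:
            continue
        wt_a = prof.se_wt[anchor - 1]
        if wt_a <= 0:
            continue
        ratio = prof.se_mut[anchor - 1] / wt_a
        if (comparator == "lt" and ratio < threshold) or (
            comparator == "gt" and ratio > threshold
        ):
            passing.append(prof)
    if not passing:
        return CosplicingProfile(anchor, comparator, threshold, [], None, None, None, None)
    wt = np.vstack([p.se_wt for p in passing])
    mut = np.vstack([p.se_mut for p in passing])
    return CosplicingProfile(
        anchor_index=anchor,
        comparator=comparator,
        threshold=threshold,
        gene_ids=[p.gene_id for p in passing],
        mean_se_wt=wt.mean(axis=0),
        mean_se_mut=mut.mean(axis=0),
        sd_se_wt=wt.std(axis=0, ddof=1) if len(passing) > 1 else np.zeros(n_introns),
        sd_se_mut=mut.std(axis=0, ddof=1) if len(passing) > 1 else np.zeros(n_introns),
    )


def expression_association(
    ranked: pd.DataFrame,
    fpkm: pd.DataFrame,
    k: int = 50,
    intron_gene: pd.DataFrame | None = None,
) -> dict:
    """Host-gene FPKM of the k worst vs k best spliced introns.

    ``ranked`` is a most-affected-first ranking (from
    :func:`splicescreen.splicing.rank_affected`); ``fpkm`` maps
    ``gene_id -> fpkm``.  ``intron_gene`` (columns ``intron_id,
    gene_id``) is needed when intron ids do not follow the
    ``<gene>.i<k>`` convention.  The test is a two-sided Welch t-test on
    log10 FPKM.  If fewer than ``k`` introns exist on either end all
    available are used and the shortfall is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fpkm_map = dict(zip(fpkm["gene_id"], fpkm["fpkm"]))

    def gene_of(intron_id: str) -> str:
        if intron_gene is not None:
            m = intron_gene.loc[intron_gene["intron_id"] == intron_id, "gene_id"]
            if len(m) == 0:
                raise KeyError(f"intron {intron_id!r} absent from intron_gene map")
            return str(m.iloc[0])
        return intron_id.rsplit(".i", 1)[0]

    ids = ranked["intron_id"].tolist()
    if len(ids) < 2 * k:
        logger.warning(
            "expression_association: only %d ranked introns for k=%d per group", len(ids), k
        )
    worst_ids = ids[: min(k, len(ids))]
    best_ids = ids[-min(k, len(ids)) :]
    worst = np.array([fpkm_map[gene_of(i)] for i in worst_ids], dtype=float)
    best = np.array([fpkm_map[gene_of(i)] for i in best_ids], dtype=float)
    lw, lb = np.log10(worst), np.log10(best)
    if np.ptp(lw) > 0 or np.ptp(lb) > 0:
        t, p = stats.ttest_ind(lw, lb, equal_var=False)
    else:
        t, p = 0.0, 1.0
    return {
        "worst_fpkm": worst,
        "best_fpkm": best,
        "worst_mean": float(worst.mean()),
        "best_mean": float(best.mean()),
        "worst_median": float(np.median(worst)),
        "best_median": float(np.median(best)),
        "t_stat": float(t),
        "p_value": float(p),
        "k": k,
    }


def cumulative_mature_fraction(per_intron_se: Sequence[float]) -> float:
    """Fraction of transcripts spliced correctly at *every* intron.

    Assumes independent splicing per intron, so the answer is the plain
    product of the per-intron efficiencies.  The empty product is 1.
    """
    total = 1.0
    for v in per_intron_se:
        if not 0.0 <= v <= 1.0 or math.isnan(v):
            raise ValueError(f"splicing efficiency {v!r} outside [0, 1]")
        total *= v
    return total


def fpkm_from_counts(counts: pd.Series, gene_lengths_nt: pd.Series) -> pd.Series:
    """FPKM from raw counts: count / (gene kb * library size in millions).

    ``gene_lengths_nt`` is the exon-union length per gene in
    nucleotides.  Used when real count matrices are supplied; in
    simulations the generator's true rate plays the FPKM role directly.
    """
    lib_millions = counts.sum() / 1e6
    kb = gene_lengths_nt.reindex(counts.index) / 1e3
    return counts / (kb * lib_millions)


def percent_splicing(spliced_signal: float, unspliced_signal: float) -> float:
    """Percent splicing from paired band intensities (e.g. RT-PCR).

    ``100 * spliced / (spliced + unspliced)``; both-zero input yields
    NA with a warning.
    """
    if spliced_signal < 0 or unspliced_signal < 0:
        raise ValueError("signals must be non-negative")
    total = spliced_signal + unspliced_signal
    if total == 0:
        warnings.warn("percent_splicing: both signals are zero; returning NA")
        return float("nan")
    return 100.0 * spliced_signal / total


def percent_retention(spliced_signal: float, unspliced_signal: float) -> float:
    """Percent intron retention: exactly ``100 - percent_splicing``."""
    return 100.0 - percent_splicing(spliced_signal, unspliced_signal)
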