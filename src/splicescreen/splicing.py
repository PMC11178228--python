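"""Per-intron splicing efficiency and its downstream comparisons.

Splicing efficiency (SE) pools the evidence at both intron boundaries:

    se = (spliced5 + spliced3) / (spliced5 + unspliced5 + spliced3 + unspliced3)

where ``spliced_b`` counts split reads whose skip matches the annotated
intron at boundary ``b`` and ``unspliced_b`` counts reads aligned
contiguously across that boundary.  Introns with total boundary
coverage below ``min_coverage`` are reported NA.  Intron retention is
``1 - se``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "splicing_efficiency",
    "decile_report",
    "assign_deciles",
    "rank_affected",
    "select_extremes",
]

_COUNT_COLS = ["spliced5", "unspliced5", "spliced3", "unspliced3"]


def splicing_efficiency(counts: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Compute SE per row of a junction-count table.

    ``counts`` needs the four boundary count columns; all other columns
    (intron_id, genotype, replicate, ...) are carried through.  Adds
    ``coverage`` (the four-count total), ``se`` (NaN below
    ``min_coverage``) and ``intron_retention``.
    """
    missing = [c for c in _COUNT_COLS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    vals = counts[_COUNT_COLS].to_numpy()
    if (vals < 0).any():
        raise ValueError("junction counts must be non-negative")
    out = counts.copy()
    coverage = vals.sum(axis=1)
    spliced = counts["spliced5"].to_numpy() + counts["spliced3"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(coverage > 0, spliced / np.maximum(coverage, 1), np.nan)
    se = np.where(coverage < min_coverage, np.nan, se)
    out["coverage"] = coverage
    out["se"] = se
    out["intron_retention"] = 1.0 - out["se"]
    return out


def assign_deciles(se_wt: pd.Series) -> pd.Series:
    """Partition introns into deciles 1..10 by wild-type SE rank.

    Decile 1 holds the least-spliced introns.  Assignment is by sorted
    rank with ties broken by intron id, so the partition is
    deterministic and decile sizes differ by at most one.
    """
    se_wt = se_wt.dropna()
    df = se_wt.rename("se").rename_axis("intron_id").reset_index()
    order = df.sort_values(["se", "intron_id"], kind="mergesort")["intron_id"]
    chunks = np.array_split(order.to_numpy(dtype=object), 10)
    labels = pd.Series(index=se_wt.index, dtype=int, name="decile")
    for d, chunk in enumerate(chunks, start=1):
        labels.loc[list(chunk)] = d
    return labels


def decile_report(
    se_wt: pd.Series, se_mut_by_genotype: dict[str, pd.Series]
) -> pd.DataFrame:
    """Compare mutant SE with wild-type SE within WT-defined deciles.

    Deciles are defined on the wild-type ranking; for each decile and
    genotype a two-sided Welch t-test compares the mutant SE values of
    that decile's introns against the wild-type values (introns NA in
    the mutant are dropped pairwise, and the drop count is logged).
    """
    deciles = assign_deciles(se_wt)
    rows = []
    for genotype, se_mut in se_mut_by_genotype.items():
        for d in range(1, 11):
            idx = deciles.index[deciles == d]
            wt_vals = se_wt.loc[idx]
            mut_vals = se_mut.reindex(idx)
            keep = mut_vals.notna()
            n_dropped = int((~keep).sum())
            if n_dropped:
                logger.info(
                    "decile %d, genotype %s: dropped %d introns NA in mutant",
                    d, genotype, n_dropped,
                )
            w = wt_vals[keep].to_numpy(float)
            m = mut_vals[keep].to_numpy(float)
            if len(m) >= 2 and (np.ptp(w) > 0 or np.ptp(m) > 0):
                t, p = stats.ttest_ind(m, w, equal_var=False)
            else:
                t, p = float("nan"), float("nan")
            rows.append(
                (
                    genotype,
                    d,
                    len(idx),
                    len(m),
                    float(w.mean()) if len(w) else float("nan"),
                    float(m.mean()) if len(m) else float("nan"),
                    float(t),
                    float(p),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype", "decile", "n_introns", "n_tested",
            "mean_se_wt", "mean_se_mut", "t_stat", "p_value",
        ],
    )


def rank_affected(
    se_wt: pd.Series, se_mut: pd.Series, metric: str = "difference"
) -> pd.DataFrame:
    """Rank introns most-affected-first.

    ``difference`` ranks by ``se_wt - se_mut`` descending; ``ratio``
    ranks by ``se_mut / se_wt`` ascending.  Introns NA in either sample
    are excluded (count logged).  Ties break by lower mutant SE, then
    lexicographic intron id, so the ranking is total and deterministic.
    """
    if metric not in ("difference", "ratio"):
        raise ValueError("metric must be 'difference' or 'ratio'")
    df = pd.DataFrame({"se_wt": se_wt, "se_mut": se_mut})
    n_all = len(df)
    df = df.dropna()
    if len(df) < n_all:
        logger.info("rank_affected: excluded %d introns NA in either sample", n_all - len(df))
    df = df.rename_axis("intron_id").reset_index()
    if metric == "difference":
        df["score"] = df["se_wt"] - df["se_mut"]
        df = df.sort_values(
            ["score", "se_mut", "intron_id"], ascending=[False, True, True], kind="mergesort"
        )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["score"] = df["se_mut"] / df["se_wt"]
        df = df.sort_values(
            ["score", "se_mut", "intron_id"], ascending=[True, True, True], kind="mergesort"
        )
    return df.reset_index(drop=True)


def select_extremes(
    ranked: pd.DataFrame, fraction: float = 0.05, direction: str = "worst"
) -> list[str]:
    """Select the extreme ``fraction`` of a most-affected-first ranking.

    Returns ``floor(fraction * N)`` intron ids (at least 1 when the
    ranking is non-empty); ``worst`` takes from the most-affected end,
    ``best`` from the least-affected end.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("worst", "best"):
        raise ValueError("direction must be 'worst' or 'best'")
    n_total = len(ranked)
    if n_total == 0:
        return []
    k = max(1, math.floor(fraction * n_total))
    ids = ranked["intron_id"].tolist()
    return ids[:k] if direction == "worst" else ids[-k:][::-1]
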