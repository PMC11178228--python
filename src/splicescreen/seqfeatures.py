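"""Splice-site composition matrices, intron length and A/T content.

Junction windows are reported 5'->3' on the annotated strand, so the
donor window of a minus-strand intron is the reverse complement of the
genomic slice at its higher-coordinate end.  Position probability
matrices use the uniform-background information convention
(``info = 2 + sum_b p_b log2 p_b`` bits, in [0, 2]).

The per-position comparison of an intron set against the all-intron
background (chi-square on base counts plus Kullback-Leibler divergence,
Benjamini-Hochberg across positions) is an added quantitative statistic
layered on top of what is usually a visual logo comparison; output
tables label it ``method=chi2-vs-background``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import IntronRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceSiteMatrix",
    "extract_junction_windows",
    "splice_site_matrix",
    "compare_to_background",
    "composition_stats",
]

_ALPHABET = "ACGT"


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def extract_junction_windows(
    introns: Sequence[IntronRecord],
    genome: Mapping[str, str],
    window: tuple[int, int] = (3, 8),
    side: str = "5p",
) -> list[str]:
    """Extract fixed windows around splice junctions.

    For the donor side (``5p``) ``window = (n_exonic, n_intronic)``;
    for the acceptor side (``3p``) ``window = (n_intronic, n_exonic)``.
    Windows that would run past a chromosome end (or past the intron
    itself on short introns) are skipped with a logged warning.
    """
    if side not in ("5p", "3p"):
        raise ValueError("side must be '5p' or '3p'")
    n_left, n_right = window
    out: list[str] = []
    n_skipped = 0
    for intr in introns:
        if intr.chrom not in genome:
            raise KeyError(f"chromosome {intr.chrom!r} absent from genome")
        seq = genome[intr.chrom]
        L = len(seq)
        if side == "5p":
            n_ex, n_in = n_left, n_right
            if intr.strand == "+":
                lo, hi = intr.start - 1 - n_ex, intr.start - 1 + n_in  # 0-based half-open
                rc = False
            else:
                lo, hi = intr.end - n_in, intr.end + n_ex
                rc = True
        else:
            n_in, n_ex = n_left, n_right
            if intr.strand == "+":
                lo, hi = intr.end - n_in, intr.end + n_ex
                rc = False
            else:
                lo, hi = intr.start - 1 - n_ex, intr.start - 1 + n_in
                rc = True
        if lo < 0 or hi > L:
            n_skipped += 1
            continue
        w = seq[lo:hi]
        out.append(_revcomp(w) if rc else w)
    if n_skipped:
        logger.warning(
            "extract_junction_windows: skipped %d truncated window(s)", n_skipped
        )
    return out


@dataclass
class SpliceSiteMatrix:
    counts: pd.DataFrame  # rows A,C,G,T x positions (N excluded)
    ppm: pd.DataFrame  # column-stochastic position probability matrix
    info: np.ndarray  # per-position information content, bits

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]


def splice_site_matrix(windows: Sequence[str]) -> SpliceSiteMatrix:
    """Build counts, PPM and information content from aligned windows.

    All windows must share one length over the {A,C,G,T,N} alphabet;
    N bases are excluded from the column counts.
    """
    if len(windows) == 0:
        raise ValueError("cannot build a matrix from an empty window set")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    arr = np.frombuffer("".join(w.upper() for w in windows).encode(), dtype="S1").reshape(
        len(windows), L
    )
    counts = pd.DataFrame(
        {p: [int((arr[:, p] == b.encode()).sum()) for b in _ALPHABET] for p in range(L)},
        index=list(_ALPHABET),
    )
    bad = set(np.unique(arr).astype(str)) - set(_ALPHABET) - {"N"}
    if bad:
        raise ValueError(f"unexpected characters in windows: {sorted(bad)}")
    totals = counts.sum(axis=0).to_numpy(float)
    if (totals == 0).any():
        raise ValueError("a column contains only N bases")
    ppm = counts / totals
    p = ppm.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return SpliceSiteMatrix(counts=counts, ppm=ppm, info=info)


def _pooled_chisquare(obs: np.ndarray, expected: np.ndarray) -> tuple[float, float, bool]:
    """Chi-square GOF with pooling of rare cells (expected < 1)."""
    obs = obs.astype(float)
    expected = expected.astype(float)
    pooled = False
    while (expected < 1.0).any() and len(obs) > 2:
        k = int(np.argmin(expected))
        rest = np.delete(np.arange(len(obs)), k)
        j = rest[np.argmin(expected[rest])]
        obs[j] += obs[k]
        expected[j] += expected[k]
        obs = np.delete(obs, k)
        expected = np.delete(expected, k)
        pooled = True
    # cells impossible under the background: observing them is divergence
    zero_exp = expected == 0
    if zero_exp.any():
        if obs[zero_exp].sum() > 0:
            return float("inf"), 0.0, pooled
        obs, expected = obs[~zero_exp], expected[~zero_exp]
        pooled = True
    if len(obs) < 2:
        return 0.0, 1.0, pooled
    # rescale expectations to the observed total (guards rounding)
    expected = expected * obs.sum() / expected.sum()
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), float(p), pooled


def compare_to_background(
    set_matrix: SpliceSiteMatrix,
    background_matrix: SpliceSiteMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position divergence of an intron set from the background.

    For each position the set's base counts are tested (chi-square)
    against expected counts under the background base frequencies;
    p-values are Benjamini-Hochberg adjusted across positions, and the
    per-position KL divergence (set vs background, bits) is reported.
    """
    if set_matrix.n_positions != background_matrix.n_positions:
        raise ValueError("matrices have different window geometries")
    rows = []
    for p_idx in range(set_matrix.n_positions):
        obs = set_matrix.counts.iloc[:, p_idx].to_numpy(float)
        bg_freq = background_matrix.ppm.iloc[:, p_idx].to_numpy(float)
        expected = bg_freq * obs.sum()
        chi2, p, pooled = _pooled_chisquare(obs, expected)
        q = set_matrix.ppm.iloc[:, p_idx].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log2(np.where(bg_freq > 0, q / bg_freq, np.inf)), 0.0)
        kl = float(terms.sum())
        rows.append((p_idx + 1, chi2, p, kl, pooled))
    out = pd.DataFrame(rows, columns=["position", "chi2", "p_value", "kl_bits", "low_count_pooled"])
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out.attrs["method"] = "chi2-vs-background"
    return out


def composition_stats(
    intron_sets: Mapping[str, Sequence[IntronRecord]],
    genome: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intron length and A/T fraction per set, with pairwise Welch tests.

    Returns ``(per_intron, pairwise)``: per-intron length/AT rows with a
    ``set`` label, and pairwise two-sided t-test p-values between sets
    for both statistics.
    """
    recs = []
    for name, introns in intron_sets.items():
        if len(introns) == 0:
            raise ValueError(f"intron set {name!r} is empty")
        for intr in introns:
            seq = genome[intr.chrom][intr.start - 1 : intr.end].upper()
            at = (seq.count("A") + seq.count("T")) / len(seq)
            recs.append((name, intr.id, intr.length, at))
    per_intron = pd.DataFrame(recs, columns=["set", "intron_id", "length", "at_fraction"])

    names = list(intron_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = per_intron[per_intron["set"] == a]
            vb = per_intron[per_intron["set"] == b]
            for stat in ("length", "at_fraction"):
                x, y = va[stat].to_numpy(float), vb[stat].to_numpy(float)
                if len(x) >= 2 and len(y) >= 2 and (np.ptp(x) > 0 or np.ptp(y) > 0):
                    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                else:
                    p = float("nan")
                rows.append((a, b, stat, p))
    pairwise = pd.DataFrame(rows, columns=["set_a", "set_b", "statistic", "p_value"])
    return per_intron, pairwise
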