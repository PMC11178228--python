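"""Synthetic intron-bearing genome generator.

Emulates the gene architecture of fission yeast: roughly 43% of genes
carry introns, genes hold up to 15 introns, and introns are short (mean
about 83 nt) with a degenerate donor site (consensus GTAAGT), a branch
point (consensus CTAAC) at a fixed offset upstream of the acceptor, and
an acceptor ending in TAG.  The invariant GT/AG terminal dinucleotides
are protected from degeneracy mutation by default so every intron stays
annotatable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seeds import child_rng
from ..annotation import GeneModel, IntronRecord

__all__ = ["GenomeSpec", "simulate_genome"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# fission-yeast-like composition: introns are A/T rich, exons milder
_INTRON_BASE_P = np.array([0.32, 0.14, 0.18, 0.36])
_EXON_BASE_P = np.array([0.30, 0.19, 0.21, 0.30])


def _default_intron_count_probs() -> np.ndarray:
    # geometric-like decay over 1..15: most intron-bearing genes have 1-2
    w = 0.52 ** np.arange(15)
    return w / w.sum()


@dataclass
class GenomeSpec:
    """Parameters of the synthetic genome.

    Lengths are in nucleotides; ``degeneracy`` is the per-position
    probability that a consensus motif base is replaced by a random
    different base.
    """

    n_genes: int = 200
    frac_intron_genes: float = 0.43
    intron_count_probs: np.ndarray = field(default_factory=_default_intron_count_probs)
    intron_len_mean: float = 83.0
    intron_len_sigma: float = 0.35  # lognormal shape on the log scale
    intron_len_min: int = 30
    exon_len_mean: float = 250.0
    exon_len_sigma: float = 0.6
    exon_len_min: int = 30
    intergenic_len_range: tuple[int, int] = (150, 400)
    consensus_5ss: str = "GTAAGT"
    consensus_bp: str = "CTAAC"
    consensus_3ss: str = "TAG"
    bp_offset: int = 10  # nt between the last BP base and the intron 3' end
    degeneracy: float = 0.15
    protect_terminal_dinucleotides: bool = True
    chrom_name: str = "chr1"

    def validate(self) -> None:
        if not 0.0 <= self.frac_intron_genes <= 1.0:
            raise ValueError("frac_intron_genes must be in [0, 1]")
        if not 0.0 <= self.degeneracy <= 1.0:
            raise ValueError("degeneracy must be in [0, 1]")
        probs = np.asarray(self.intron_count_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 1 or len(probs) > 15:
            raise ValueError("intron_count_probs must cover intron counts 1..15")
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("intron_count_probs must be a probability vector")
        if self.intron_len_min < len(self.consensus_5ss) + len(self.consensus_bp) + self.bp_offset + len(self.consensus_3ss):
            raise ValueError("intron_len_min too small to hold the splice motifs")
        if self.exon_len_min < 1 or self.intron_len_min < 1:
            raise ValueError("all lengths must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


def _revcomp(seq: np.ndarray) -> np.ndarray:
    u8 = seq.view(np.uint8)
    return _COMP_TABLE[u8[::-1]].view("S1")


def _random_bases(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=p)


def _stamp_motif(
    seq: np.ndarray,
    offset: int,
    motif: str,
    rng: np.random.Generator,
    degeneracy: float,
    protected: tuple[int, ...] = (),
) -> None:
    """Write ``motif`` into ``seq`` at ``offset`` with per-position mutation."""
    for i, base in enumerate(motif):
        if degeneracy > 0 and i not in protected and rng.random() < degeneracy:
            choices = [b for b in "ACGT" if b != base]
            seq[offset + i] = rng.choice(choices).encode()
        else:
            seq[offset + i] = base.encode()


def _lognormal_lengths(
    rng: np.random.Generator, n: int, mean: float, sigma: float, minimum: int
) -> np.ndarray:
    # parameterize so the distribution mean equals ``mean``
    mu = np.log(mean) - sigma**2 / 2.0
    lens = np.maximum(np.round(rng.lognormal(mu, sigma, size=n)).astype(int), minimum)
    return lens


def _make_intron(spec: GenomeSpec, length: int, rng: np.random.Generator) -> np.ndarray:
    seq = _random_bases(rng, length, _INTRON_BASE_P)
    protected_5 = (0, 1) if spec.protect_terminal_dinucleotides else ()
    _stamp_motif(seq, 0, spec.consensus_5ss, rng, spec.degeneracy, protected_5)
    bp_start = length - spec.bp_offset - len(spec.consensus_bp)
    _stamp_motif(seq, bp_start, spec.consensus_bp, rng, spec.degeneracy)
    n3 = len(spec.consensus_3ss)
    if spec.protect_terminal_dinucleotides:
        protected_3 = tuple(range(n3 - 2, n3))
    else:
        protected_3 = ()
    _stamp_motif(seq, length - n3, spec.consensus_3ss, rng, spec.degeneracy, protected_3)
    return seq


def simulate_genome(
    spec: GenomeSpec, seed: int
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a genome and its gene models.

    Returns ``(sequences, genes)`` where ``sequences`` maps chromosome
    name to sequence and ``genes`` carry exon/intron coordinates
    (1-based inclusive).  The same ``(spec, seed)`` pair is
    byte-reproducible.
    """
    spec.validate()
    rng = child_rng(seed, "genome")
    chrom_parts: list[np.ndarray] = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based running offset into the chromosome

    lo, hi = spec.intergenic_len_range
    for gi in range(spec.n_genes):
        gap = int(rng.integers(lo, hi + 1))
        chrom_parts.append(_random_bases(rng, gap, _EXON_BASE_P))
        pos += gap

        has_introns = rng.random() < spec.frac_intron_genes
        if has_introns:
            n_introns = 1 + int(
                rng.choice(len(spec.intron_count_probs), p=np.asarray(spec.intron_count_probs))
            )
        else:
            n_introns = 0
        exon_lens = _lognormal_lengths(
            rng, n_introns + 1, spec.exon_len_mean, spec.exon_len_sigma, spec.exon_len_min
        )
        intron_lens = _lognormal_lengths(
            rng, n_introns, spec.intron_len_mean, spec.intron_len_sigma, spec.intron_len_min
        )
        strand = "+" if rng.random() < 0.5 else "-"

        # assemble the transcript-oriented gene sequence
        parts: list[np.ndarray] = []
        exon_bounds_t: list[tuple[int, int]] = []  # 0-based half-open, transcript orientation
        intron_bounds_t: list[tuple[int, int]] = []
        t = 0
        for k in range(n_introns + 1):
            parts.append(_random_bases(rng, exon_lens[k], _EXON_BASE_P))
            exon_bounds_t.append((t, t + int(exon_lens[k])))
            t += int(exon_lens[k])
            if k < n_introns:
                parts.append(_make_intron(spec, int(intron_lens[k]), rng))
                intron_bounds_t.append((t, t + int(intron_lens[k])))
                t += int(intron_lens[k])
        gene_seq = np.concatenate(parts) if parts else np.empty(0, dtype="S1")
        gene_len = len(gene_seq)

        if strand == "-":
            genomic_seq = _revcomp(gene_seq)
        else:
            genomic_seq = gene_seq
        chrom_parts.append(genomic_seq)

        gid = f"gene{gi + 1:05d}"
        g_start, g_end = pos + 1, pos + gene_len  # 1-based inclusive

        def to_genomic(tb: tuple[int, int]) -> tuple[int, int]:
            s_t, e_t = tb  # transcript coords, 0-based half-open
            if strand == "+":
                return pos + s_t + 1, pos + e_t
            return pos + gene_len - e_t + 1, pos + gene_len - s_t

        exons = sorted(to_genomic(tb) for tb in exon_bounds_t)
        introns = [
            IntronRecord(gid, k + 1, spec.chrom_name, *to_genomic(tb), strand)
            for k, tb in enumerate(intron_bounds_t)
        ]
        genes.append(GeneModel(gid, spec.chrom_name, g_start, g_end, strand, exons, introns))
        pos += gene_len

    sequence = (
        b"".join(p.tobytes() for p in chrom_parts).decode() if chrom_parts else ""
    )
    sequences = {spec.chrom_name: sequence} if spec.n_genes > 0 else {}
    return sequences, genes
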