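"""Junction-read counting from SAM alignments.

A split read supports the *spliced* form of an intron when one of its
CIGAR skip blocks (N) matches the annotated intron exactly and the read
has at least ``min_overhang`` aligned bases on each side of the skip.
A contiguously aligned read supports the *unspliced* form at a boundary
when it covers ``min_overhang`` bases on each side of that exon-intron
junction within a single gapless alignment stretch.  Each read counts
at most once per boundary.  Skips matching no annotated intron are
tallied to a novel-junction log rather than raising.

Boundary labels are transcript-oriented: for a minus-strand intron the
5' (donor) boundary sits at the higher genomic coordinate.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .annotation import IntronRecord

logger = logging.getLogger(__name__)

__all__ = ["count_junction_reads"]

# CIGAR operation codes
_MATCH_OPS = {0, 7, 8}  # M, =, X
_DEL = 2  # D: consumes reference, still contiguous on the genome
_SKIP = 3  # N: splice junction


def _reference_segments(read: pysam.AlignedSegment) -> list[tuple[int, int, bool]]:
    """Decompose an alignment into reference intervals.

    Returns ``(start, end, is_skip)`` triples, 0-based half-open, where
    contiguous M/=/X/D runs are merged into one aligned interval and
    each N run is its own skip interval.
    """
    segs: list[tuple[int, int, bool]] = []
    pos = read.reference_start
    cur_start: int | None = None
    for op, length in read.cigartuples or []:
        if op in _MATCH_OPS or op == _DEL:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == _SKIP:
            if cur_start is not None:
                segs.append((cur_start, pos, False))
                cur_start = None
            segs.append((pos, pos + length, True))
            pos += length
        # I, S, H, P consume no reference
    if cur_start is not None:
        segs.append((cur_start, pos, False))
    return segs


def count_junction_reads(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    introns: Sequence[IntronRecord],
    min_overhang: int = 6,
) -> pd.DataFrame:
    """Tally spliced/unspliced junction evidence for annotated introns.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam
    records.  Returns one row per intron with columns
    ``spliced5, unspliced5, spliced3, unspliced3`` plus an attached
    ``.attrs["novel_junctions"]`` Counter of unannotated skips.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    by_coord: dict[tuple[str, int, int], IntronRecord] = {
        (i.chrom, i.start, i.end): i for i in introns
    }
    counts = {
        i.id: {"spliced5": 0, "unspliced5": 0, "spliced3": 0, "unspliced3": 0}
        for i in introns
    }
    novel: Counter[tuple[str, int, int]] = Counter()

    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        reads: Iterable[pysam.AlignedSegment] = handle.fetch(until_eof=True)
    else:
        reads = alignments

    for read in reads:
        if read.is_unmapped or read.cigartuples is None:
            continue
        chrom = read.reference_name
        segs = _reference_segments(read)
        # spliced support: skip matching an annotated intron with flanks
        for k, (s, e, is_skip) in enumerate(segs):
            if not is_skip:
                continue
            left_ok = k > 0 and not segs[k - 1][2] and (segs[k - 1][1] - segs[k - 1][0]) >= min_overhang
            right_ok = (
                k + 1 < len(segs)
                and not segs[k + 1][2]
                and (segs[k + 1][1] - segs[k + 1][0]) >= min_overhang
            )
            if not (left_ok and right_ok):
                continue
            key = (chrom, s + 1, e)  # to 1-based inclusive
            intr = by_coord.get(key)
            if intr is None:
                novel[key] += 1
                continue
            c = counts[intr.id]
            c["spliced5"] += 1
            c["spliced3"] += 1
        # unspliced support: gapless coverage across a boundary
        aligned = [(s, e) for s, e, is_skip in segs if not is_skip]
        for intr in introns:
            if intr.chrom != chrom:
                continue
            # genomic boundary positions (1-based first intronic base / last)
            start_b = intr.start  # exon|intron junction at the genomic start
            end_b = intr.end  # intron|exon junction at the genomic end
            covers_start = any(
                s + 1 <= start_b - min_overhang and e >= start_b + min_overhang - 1
                for s, e in aligned
            )
            covers_end = any(
                s + 1 <= end_b - min_overhang + 1 and e >= end_b + min_overhang
                for s, e in aligned
            )
            if not (covers_start or covers_end):
                continue
            c = counts[intr.id]
            donor_at_start = intr.strand == "+"
            if covers_start:
                c["unspliced5" if donor_at_start else "unspliced3"] += 1
            if covers_end:
                c["unspliced3" if donor_at_start else "unspliced5"] += 1

    out = pd.DataFrame.from_dict(counts, orient="index").rename_axis("intron_id").reset_index()
    out.attrs["novel_junctions"] = novel
    if novel:
        logger.info("count_junction_reads: %d novel junction(s) observed", sum(novel.values()))
    return out
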