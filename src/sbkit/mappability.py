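"""Per-TA-site mappability and read filtering.

Screen reads start at the ITR/genome junction adjacent to the target
TA, so whether a read can be placed unambiguously depends on how much
unique sequence extends from that TA in the read's direction.  For
every TA site and strand, mock reads anchored at the TA are generated
at lengths 10..65 bp in 5 bp steps and aligned back to the genome; the
mappability of the site/strand is the minimum length at which mapping
is *accurate and unique*: the originating locus is hit with alignment
score above ``score_min``, and no other locus is hit with fewer than
``alt_mismatch_limit`` mismatches.  Sites failing at every tested
length are recorded as unmappable, and experimental reads shorter than
the site's minimum (or at unmappable sites) are discarded.

The built-in aligner is an exhaustive both-strand Hamming scan (match
+1 / mismatch -1, so a perfect L-mer scores L) suitable for toy
genomes; external aligners can stand in through the
:class:`AlignerAdapter` protocol for larger references.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, TAIndex, build_ta_index, reverse_complement

__all__ = [
    "MockRead",
    "AlignmentHit",
    "AlignerAdapter",
    "ExhaustiveAligner",
    "generate_mock_reads",
    "min_unique_length",
    "filter_reads",
    "DEFAULT_LENGTHS",
    "UNMAPPABLE",
]

DEFAULT_LENGTHS: Tuple[int, ...] = tuple(range(10, 70, 5))  # 10..65
UNMAPPABLE = -1  # sentinel in numeric outputs; rendered as NA in TSV

Site = Tuple[str, int]


@dataclass(frozen=True)
class MockRead:
    """A genome-derived read anchored at a TA site.

    Plus-strand reads run from the TA rightward; minus-strand reads
    are the reverse complement of the window ending at the TA's right
    edge.  Either way the read begins ``TA...``.
    """

    chrom: str
    ta_pos: int
    strand: str
    length: int
    sequence: str


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    pos: int  # plus-strand start of the match footprint
    strand: str
    mismatches: int
    score: int


class AlignerAdapter(Protocol):
    """Contract for pluggable aligners: given a read sequence, report
    candidate placements ordered best-score-first."""

    def align(self, sequence: str, max_hits: int = 10) -> List[AlignmentHit]:
        ...


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


class ExhaustiveAligner:
    """Exhaustive Hamming-distance scan of both genome strands.

    Every position whose window differs from the read in at most
    ``max_mismatches`` bases is a hit; N bases never match anything.
    Score is ``matches - mismatches`` (= L - 2m).  Hits are returned
    best-score-first, capped at ``max_hits``.
    """

    def __init__(self, genome: ReferenceGenome, max_mismatches: int = 2) -> None:
        self.genome = genome
        self.max_mismatches = max_mismatches
        self._arrays = {name: _encode(seq) for name, seq in genome.sequences.items()}
        self._has_n = {name: bool((a == _N).any()) for name, a in self._arrays.items()}

    def _scan(self, read_arr: np.ndarray, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        ref = self._arrays[chrom]
        L = len(read_arr)
        if L > len(ref):
            return np.empty(0, np.int64), np.empty(0, np.int64)
        n_win = len(ref) - L + 1
        check_n = self._has_n[chrom] or bool((read_arr == _N).any())
        # column-wise accumulation over contiguous slices: much faster
        # than reducing a strided (n_win, L) window view
        mism = np.zeros(n_win, dtype=np.int32)
        for j in range(L):
            col = ref[j : j + n_win]
            diff = col != read_arr[j]
            if check_n:
                # N never matches, including N vs N
                diff = diff | (col == _N) | (read_arr[j] == _N)
            mism += diff
        keep = np.flatnonzero(mism <= self.max_mismatches)
        return keep.astype(np.int64), mism[keep].astype(np.int64)

    def align(self, sequence: str, max_hits: int = 10) -> List[AlignmentHit]:
        read = _encode(sequence.upper())
        rc = _encode(reverse_complement(sequence.upper()))
        L = len(read)
        hits: List[AlignmentHit] = []
        for chrom in self._arrays:
            for strand, arr in (("+", read), ("-", rc)):
                pos, mism = self._scan(arr, chrom)
                for p, m in zip(pos, mism):
                    hits.append(
                        AlignmentHit(chrom, int(p), strand, int(m), L - 2 * int(m))
                    )
        hits.sort(key=lambda h: (-h.score, h.chrom, h.pos, h.strand))
        return hits[:max_hits]


def generate_mock_reads(
    genome: ReferenceGenome,
    ta_index: Optional[TAIndex] = None,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    positions: Optional[Mapping[str, Iterable[int]]] = None,
    anchor_offset: int = 0,
) -> Iterable[MockRead]:
    """Yield mock reads for every TA site, both strands, all lengths.

    Reads that would extend past a sequence end are skipped.
    ``positions`` restricts generation to a subset of TA sites per
    sequence; ``anchor_offset`` shifts the read start relative to the
    TA (0 anchors exactly at it).
    """
    if list(lengths) != sorted(lengths):
        raise ValueError("lengths must be sorted ascending")
    index = ta_index if ta_index is not None else build_ta_index(genome)
    for chrom, all_pos in index.positions.items():
        seq = genome[chrom]
        n = len(seq)
        pos_iter = positions.get(chrom, ()) if positions is not None else all_pos
        for p in pos_iter:
            p = int(p) + anchor_offset
            for L in lengths:
                if p + L <= n:
                    yield MockRead(chrom, p, "+", L, seq[p : p + L])
                if p + 2 - L >= 0:
                    yield MockRead(
                        chrom, p, "-", L, reverse_complement(seq[p + 2 - L : p + 2])
                    )


def _origin_hit_pos(read: MockRead) -> int:
    """Plus-strand start of the read's true placement."""
    return read.ta_pos if read.strand == "+" else read.ta_pos + 2 - read.length


def min_unique_length(
    genome: ReferenceGenome,
    ta_index: Optional[TAIndex] = None,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    score_min: int = 10,
    alt_mismatch_limit: int = 2,
    positions: Optional[Mapping[str, Iterable[int]]] = None,
    aligner: Optional[AlignerAdapter] = None,
    max_hits: int = 50,
) -> pd.DataFrame:
    """Minimum accurate-and-unique mapping length per TA site and strand.

    A length qualifies iff the originating locus is hit with score
    strictly above ``score_min`` AND no other locus is hit with fewer
    than ``alt_mismatch_limit`` mismatches (a near-perfect alternative
    placement makes the read ambiguous).  Qualification is evaluated
    independently at each tested length — monotonicity in length is
    not assumed — and the minimum over the grid is reported, or the
    unmappable sentinel when no length qualifies.

    Returns a DataFrame with columns ``chrom, pos, strand, min_len``
    (``min_len == -1`` meaning unmappable).
    """
    index = ta_index if ta_index is not None else build_ta_index(genome)
    if aligner is None:
        aligner = ExhaustiveAligner(genome, max_mismatches=max(alt_mismatch_limit, 2))
    best: Dict[Tuple[str, int, str], int] = {}
    for read in generate_mock_reads(genome, index, lengths, positions):
        key = (read.chrom, read.ta_pos, read.strand)
        if best.get(key, UNMAPPABLE) != UNMAPPABLE:
            continue  # already found its minimum (lengths iterate ascending)
        best.setdefault(key, UNMAPPABLE)
        origin = (read.chrom, _origin_hit_pos(read), read.strand)
        hits = aligner.align(read.sequence, max_hits=max_hits)
        at_origin = [h for h in hits if (h.chrom, h.pos, h.strand) == origin]
        accurate = any(h.score > score_min for h in at_origin)
        ambiguous = any(
            h.mismatches < alt_mismatch_limit
            for h in hits
            if (h.chrom, h.pos, h.strand) != origin
        )
        if accurate and not ambiguous:
            best[key] = read.length
    # sites whose reads were all truncated never appear in `best`
    rows = []
    for chrom, all_pos in index.positions.items():
        pos_iter = positions.get(chrom, ()) if positions is not None else all_pos
        for p in pos_iter:
            for strand in "+-":
                rows.append(
                    (chrom, int(p), strand, best.get((chrom, int(p), strand), UNMAPPABLE))
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "min_len"])


def filter_reads(
    reads: pd.DataFrame,
    mappability: pd.DataFrame,
) -> Tuple[pd.DataFrame, Counter]:
    """Discard experimental reads below the site's minimum mapping length.

    ``reads`` needs columns ``chrom, pos, strand, length``.  A read is
    retained iff a mappability record exists for its (chrom, pos,
    strand) with ``min_len != -1`` and ``length >= min_len``.  Returns
    the retained rows and a per-reason discard log
    (``unmappable_site``, ``below_min_length``, ``no_record``).
    """
    lookup = {
        (r.chrom, int(r.pos), r.strand): int(r.min_len)
        for r in mappability.itertuples()
    }
    keep_mask = []
    log: Counter = Counter()
    for r in reads.itertuples():
        key = (r.chrom, int(r.pos), r.strand)
        if key not in lookup:
            log["no_record"] += 1
            keep_mask.append(False)
        elif lookup[key] == UNMAPPABLE:
            log["unmappable_site"] += 1
            keep_mask.append(False)
        elif int(r.length) < lookup[key]:
            log["below_min_length"] += 1
            keep_mask.append(False)
        else:
            log["retained"] += 1
            keep_mask.append(True)
    return reads.loc[keep_mask].reset_index(drop=True), log
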