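"""Reference sequences, TA-dinucleotide indexing, motif scanning, and
interval annotation.

The Sleeping Beauty (SB) transposase integrates exclusively at TA
dinucleotides, so the TA index is the universe of potential insertion
sites for every downstream computation (bias windows, mappability,
simulation).  Coordinates are 0-based half-open throughout the library;
report writers convert to 1-based inclusive (see :mod:`sbkit.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "ReferenceGenome",
    "TAIndex",
    "AnnotationSet",
    "GenomicInterval",
    "MotifHit",
    "build_ta_index",
    "scan_motif",
    "classify_site",
    "ta_composition",
    "reverse_complement",
    "IUPAC_CODES",
    "FOOTPRINT_VARIANTS",
    "FOOTPRINT_MOTIF",
    "HPYCH4III_MOTIF",
]

# IUPAC codes accepted in motif patterns.  N deliberately does not match
# an N base in the genome: assembly gaps never count as motif hits.
IUPAC_CODES: Dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "W": "AT",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNWacgtnw", "TGCANWtgcanw")

# Canonical SB excision-footprint 7-mers (duplicated TA flanking the 3-bp
# ITR-derived remnant) and the HpyCH4III recognition site they contain.
FOOTPRINT_VARIANTS: Tuple[str, str] = ("TACAGTA", "TACTGTA")
FOOTPRINT_MOTIF = "TACWGTA"
HPYCH4III_MOTIF = "ACNGT"

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide or IUPAC (A,C,G,T,N,W) string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """A set of named uppercase nucleotide sequences (alphabet ACGTN).

    Parameters
    ----------
    sequences
        Mapping of sequence name to nucleotide string.  Sequences are
        uppercased on construction; any character outside ``ACGTN``
        raises ``ValueError``.
    """

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        clean: Dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = str(seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = seq
        object.__setattr__(self, "sequences", clean)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def names(self) -> List[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class TAIndex:
    """Sorted 0-based positions of the T of every plus-strand ``TA``.

    TA is its own reverse complement, so a single strandless index
    covers both strands.
    """

    positions: Mapping[str, np.ndarray]

    @property
    def total_ta_count(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of indexed TA sites with T-coordinate in [start, end)."""
        pos = self.positions[chrom]
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def in_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def is_ta(self, chrom: str, pos: int) -> bool:
        arr = self.positions[chrom]
        i = int(np.searchsorted(arr, pos))
        return i < len(arr) and arr[i] == pos


def build_ta_index(genome: ReferenceGenome) -> TAIndex:
    """Index every plus-strand TA dinucleotide in *genome*.

    Raises
    ------
    ValueError
        If the genome contains no sequences.
    """
    if not genome.sequences:
        raise ValueError("no sequences")
    positions: Dict[str, np.ndarray] = {}
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            positions[name] = np.empty(0, dtype=np.int64)
            continue
        hits = (arr[:-1] == ord("T")) & (arr[1:] == ord("A"))
        positions[name] = np.flatnonzero(hits).astype(np.int64)
    return TAIndex(positions=positions)


@dataclass(frozen=True)
class MotifHit:
    """A motif match; ``start`` is always the plus-strand coordinate of
    the match footprint, even for minus-strand hits."""

    chrom: str
    start: int
    strand: str
    motif: str


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        expand = IUPAC_CODES[ch]
        parts.append(expand if len(expand) == 1 else f"[{expand}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(
    genome: ReferenceGenome, motif: str, both_strands: bool = True
) -> List[MotifHit]:
    """Find every occurrence of an IUPAC *motif* (codes A,C,G,T,N,W).

    Minus-strand hits are located by scanning the plus strand for the
    motif's reverse complement and are reported at the plus-strand
    coordinates of the match footprint.  Palindromic motifs therefore
    yield one hit per strand; no collapsing is done.
    """
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(reverse_complement(motif)) if both_strands else None
    hits: List[MotifHit] = []
    for name, seq in genome.sequences.items():
        for m in fwd.finditer(seq):
            hits.append(MotifHit(name, m.start(), "+", motif))
        if rev is not None:
            for m in rev.finditer(seq):
                hits.append(MotifHit(name, m.start(), "-", motif))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    feature: str  # exon | intron | gene | repeat
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )


class AnnotationSet:
    """Interval annotation (exon/intron/gene/repeat), 0-based half-open.

    Parameters
    ----------
    intervals
        Iterable of :class:`GenomicInterval` or (chrom, start, end,
        feature[, label]) tuples.
    sequence_names
        Optional set of valid sequence names; queries on other names
        raise ``KeyError``.  When omitted, any name is accepted.
    """

    FEATURES = ("exon", "intron", "gene", "repeat")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval | tuple],
        sequence_names: Optional[Iterable[str]] = None,
    ) -> None:
        self.intervals: List[GenomicInterval] = []
        for iv in intervals:
            if not isinstance(iv, GenomicInterval):
                iv = GenomicInterval(*iv)
            if iv.feature not in self.FEATURES:
                raise ValueError(f"unknown feature {iv.feature!r}")
            self.intervals.append(iv)
        self.sequence_names = (
            frozenset(sequence_names) if sequence_names is not None else None
        )
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for iv in self.intervals:
            key = (iv.chrom, iv.feature)
            self._trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, iv)

    def _check_chrom(self, chrom: str) -> None:
        if self.sequence_names is not None and chrom not in self.sequence_names:
            raise KeyError(f"unknown sequence name {chrom!r}")

    def overlapping(
        self, chrom: str, start: int, end: int, feature: Optional[str] = None
    ) -> List[GenomicInterval]:
        """Intervals intersecting [start, end), optionally of one feature."""
        self._check_chrom(chrom)
        feats = [feature] if feature else self.FEATURES
        out = []
        for f in feats:
            tree = self._trees.get((chrom, f))
            if tree is not None:
                out.extend(iv.data for iv in tree.overlap(start, end))
        return out

    def covers(self, chrom: str, pos: int, feature: str) -> bool:
        self._check_chrom(chrom)
        tree = self._trees.get((chrom, feature))
        return bool(tree is not None and tree.overlaps_point(pos))

    def labels_overlapping(self, chrom: str, start: int, end: int, feature: str = "gene") -> List[str]:
        return sorted({iv.label for iv in self.overlapping(chrom, start, end, feature) if iv.label})


def classify_site(chrom: str, pos: int, annot: AnnotationSet) -> str:
    """Feature class of one position: ``exon`` > ``intron`` > ``intergenic``.

    Exon takes precedence when exon and intron overlap; positions inside
    a gene but no exon are intronic; everything outside gene intervals
    is intergenic.
    """
    if annot.covers(chrom, pos, "exon"):
        return "exon"
    if annot.covers(chrom, pos, "gene") or annot.covers(chrom, pos, "intron"):
        if annot.covers(chrom, pos, "intron"):
            return "intron"
        # inside a gene with no sub-feature at pos: intronic by exclusion
        return "intron"
    return "intergenic"


def ta_composition(index: TAIndex, annot: AnnotationSet) -> Dict[str, float]:
    """Fraction of TA sites falling in exon / intron / intergenic space.

    Raises
    ------
    ValueError
        If the index contains no TA sites.
    """
    total = index.total_ta_count
    if total == 0:
        raise ValueError("empty TA index")
    counts = {"exon": 0, "intron": 0, "intergenic": 0}
    for chrom, positions in index.positions.items():
        for pos in positions:
            counts[classify_site(chrom, int(pos), annot)] += 1
    return {k: v / total for k, v in counts.items()}
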