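"""Transposon-footprint calling from footprint-library site tables.

The footprint library amplifies every locus carrying the excision
7-mer consensus (TACWGTA), so the raw site lists are dominated by
background: endogenous occurrences of the motif and HpyCH4III sites at
surviving ITR/genome junctions.  The caller applies, in order,

1. subtraction of sites present in the matched normal sample,
2. removal of sites in the sample's clonally-expanded insertion set,
3. removal of sites recurring in more than one tumor (footprints are
   assumed private to a sample; recurrent sites are dropped from all),
4. the dual-strand rule: >= 1 read on each strand, which guarantees an
   intact 7-mer spanning the locus.

Surviving candidates are tiered by sequencing depth against a clonal
reference, annotated by feature class, and scaled by tier-specific
validation rates to estimate the number of bona fide footprints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationSet, classify_site

__all__ = [
    "FootprintCandidate",
    "ValidationRecord",
    "EnrichmentTestResult",
    "call_candidates",
    "assign_confidence",
    "estimate_true_footprints",
    "annotate_candidates",
    "exon_enrichment_test",
    "pooled_validation_rate",
]

Site = Tuple[str, int]


@dataclass(frozen=True)
class FootprintCandidate:
    """A putative excision-footprint locus in one tumor."""

    sample_id: str
    chrom: str
    pos: int  # TA position (T of the duplicated TA), 0-based
    plus_reads: int
    minus_reads: int
    confidence: Optional[str] = None  # "high" | "low"
    feature_class: Optional[str] = None  # exon | intron | intergenic

    @property
    def depth(self) -> int:
        return self.plus_reads + self.minus_reads


@dataclass(frozen=True)
class ValidationRecord:
    """PCR-validation outcome for one confidence tier."""

    confidence: str
    n_tested: int
    n_confirmed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_confirmed <= self.n_tested:
            raise ValueError("need 0 <= n_confirmed <= n_tested")

    @property
    def rate(self) -> float:
        if self.n_tested == 0:
            raise ValueError(f"no tested sites in tier {self.confidence!r}")
        return self.n_confirmed / self.n_tested


@dataclass(frozen=True)
class EnrichmentTestResult:
    observed: int
    total: int
    expected_proportion: float
    z: float
    p_value: float


def _as_site_dict(table) -> Dict[Site, Tuple[int, int]]:
    """Normalize a site table to {(chrom, pos): (plus_reads, minus_reads)}."""
    if isinstance(table, pd.DataFrame):
        return {
            (str(r.chrom), int(r.pos)): (int(r.plus_reads), int(r.minus_reads))
            for r in table.itertuples()
        }
    return {
        (str(c), int(p)): (int(plus), int(minus))
        for (c, p), (plus, minus) in dict(table).items()
    }


def call_candidates(
    tumor_tables: Mapping[str, object],
    normal_table: object,
    clonal_insertions: Optional[Mapping[str, Iterable[Site]]] = None,
) -> Dict[str, List[FootprintCandidate]]:
    """Run the sequential footprint filters on per-sample site tables.

    Parameters
    ----------
    tumor_tables
        Per-sample tables: DataFrame with columns ``chrom, pos,
        plus_reads, minus_reads`` or dict ``{(chrom, pos): (plus,
        minus)}``.
    normal_table
        Same schema, for the tissue-matched normal lacking SB
        transposition.  The pipeline is undefined without it.
    clonal_insertions
        Per-sample sets of clonally expanded insertion sites.

    Returns
    -------
    dict mapping sample id to candidates sorted by coordinate.
    """
    if normal_table is None:
        raise ValueError("a matched normal site table is required")
    normal_sites = set(_as_site_dict(normal_table))
    tumors = {s: _as_site_dict(t) for s, t in tumor_tables.items()}
    clonal = {s: set(v) for s, v in (clonal_insertions or {}).items()}

    # sites seen in more than one tumor are dropped from every sample
    seen: Dict[Site, int] = {}
    for sites in tumors.values():
        for site in sites:
            seen[site] = seen.get(site, 0) + 1
    redundant = {site for site, n in seen.items() if n > 1}

    out: Dict[str, List[FootprintCandidate]] = {}
    for sample, sites in tumors.items():
        keep: List[FootprintCandidate] = []
        excl = normal_sites | clonal.get(sample, set()) | redundant
        for (chrom, pos), (plus, minus) in sites.items():
            if (chrom, pos) in excl:
                continue
            if plus < 1 or minus < 1:
                continue
            keep.append(FootprintCandidate(sample, chrom, pos, plus, minus))
        keep.sort(key=lambda c: (c.chrom, c.pos))
        out[sample] = keep
    return out


def assign_confidence(
    candidates: Sequence[FootprintCandidate],
    clonal_site_depths: Sequence[float],
    percentile: float = 25.0,
) -> List[FootprintCandidate]:
    """Tier candidates by depth against the clonal-insertion reference.

    A candidate is high confidence iff its total depth (plus + minus)
    is at least the ``percentile``-th percentile (linear interpolation)
    of the read depths observed at simultaneously sequenced clonally
    expanded insertion sites.
    """
    if len(clonal_site_depths) == 0:
        raise ValueError("clonal reference depths must be non-empty")
    threshold = float(np.percentile(np.asarray(clonal_site_depths, float), percentile))
    return [
        replace(c, confidence="high" if c.depth >= threshold else "low")
        for c in candidates
    ]


def pooled_validation_rate(records: Iterable[ValidationRecord]) -> Dict[str, float]:
    """Per-tier confirmation rates pooled across samples."""
    tested: Dict[str, int] = {}
    confirmed: Dict[str, int] = {}
    for rec in records:
        tested[rec.confidence] = tested.get(rec.confidence, 0) + rec.n_tested
        confirmed[rec.confidence] = confirmed.get(rec.confidence, 0) + rec.n_confirmed
    out = {}
    for tier, n in tested.items():
        if n == 0:
            raise ValueError(f"no tested sites in tier {tier!r}")
        out[tier] = confirmed[tier] / n
    return out


def estimate_true_footprints(
    n_high: int,
    n_low: int,
    validation: Iterable[ValidationRecord],
) -> int:
    """Estimated bona fide footprints in one sample.

    Scales each tier's candidate count by its pooled validation rate
    and rounds the combined estimate up to the next whole footprint:
    ``ceil(n_high * r_high + n_low * r_low)``.
    """
    rates = pooled_validation_rate(validation)
    for tier in ("high", "low"):
        if tier not in rates:
            raise ValueError(f"validation records missing tier {tier!r}")
    return math.ceil(n_high * rates["high"] + n_low * rates["low"])


def annotate_candidates(
    candidates: Mapping[str, Sequence[FootprintCandidate]],
    annot: AnnotationSet,
) -> Tuple[Dict[str, List[FootprintCandidate]], pd.DataFrame]:
    """Attach feature classes and build the per-sample summary table.

    The summary has one row per sample plus a pooled ``total`` row with
    columns ``sample, n_candidates, n_intron, pct_intron, n_exon,
    pct_exon`` (percentages to one decimal place).
    """
    annotated: Dict[str, List[FootprintCandidate]] = {}
    rows = []
    tot_n = tot_intron = tot_exon = 0
    for sample, cands in candidates.items():
        new = [
            replace(c, feature_class=classify_site(c.chrom, c.pos, annot))
            for c in cands
        ]
        annotated[sample] = new
        n = len(new)
        n_intron = sum(1 for c in new if c.feature_class == "intron")
        n_exon = sum(1 for c in new if c.feature_class == "exon")
        tot_n += n
        tot_intron += n_intron
        tot_exon += n_exon
        rows.append(_summary_row(sample, n, n_intron, n_exon))
    rows.append(_summary_row("total", tot_n, tot_intron, tot_exon))
    summary = pd.DataFrame(
        rows,
        columns=["sample", "n_candidates", "n_intron", "pct_intron", "n_exon", "pct_exon"],
    )
    return annotated, summary


def _summary_row(sample: str, n: int, n_intron: int, n_exon: int) -> tuple:
    pct = lambda k: round(100.0 * k / n, 1) if n else 0.0
    return (sample, n, n_intron, pct(n_intron), n_exon, pct(n_exon))


def exon_enrichment_test(k: int, n: int, p0: float) -> EnrichmentTestResult:
    """Two-tailed z-test of the exonic candidate fraction against the
    exonic TA fraction of the genome.

    Uses the one-sample proportion form (the two-proportion test with
    an effectively infinite reference sample reduces to it):
    ``z = (k/n - p0) / sqrt(p0 (1 - p0) / n)``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n * p0 < 5 or n * (1 - p0) < 5:
        warnings.warn(
            "normal approximation is unreliable: n*p0 or n*(1-p0) below 5",
            stacklevel=2,
        )
    z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return EnrichmentTestResult(k, n, p0, z, min(p, 1.0))
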