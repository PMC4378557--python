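"""Semi-quantitative clonality stratification of insertion sites.

Read counts from LM-PCR libraries track relative template abundance
well enough to sort a tumor's insertion sites into broad clonality
groups, but not to rank sites within a group.  The workflow here:
normalize each site's read count to the most abundant site (top site
= 100%), group sites into abundance bins, and estimate a per-bin false
discovery rate from replicate libraries by leave-one-out comparison —
each replicate in turn is the "test set", and the sites found in both
remaining replicates form the "true-positive set".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import AnnotationSet

__all__ = [
    "NormalizedProfile",
    "FDRTable",
    "DEFAULT_BIN_EDGES",
    "normalize_to_max",
    "group_by_abundance",
    "estimate_fdr",
    "count_ligation_points",
    "clonal_expansion_metrics",
]

Site = Tuple[str, int]

# Half-open-on-the-left bins (lo, hi]: the 5% boundary is the
# zero-FDR threshold; the 12.5 and 50 edges follow the spike-in tiers.
DEFAULT_BIN_EDGES: Tuple[float, ...] = (0.0, 1.0, 5.0, 12.5, 50.0, 100.0)


@dataclass
class NormalizedProfile:
    """Per-site abundance as percent of the sample's top site."""

    sample_id: str
    values: Dict[Site, float]  # site -> % of max, in (0, 100]
    metric: str = "reads"  # "reads" | "ligation_points"

    def sites(self) -> set:
        return set(self.values)


@dataclass
class FDRTable:
    """Leave-one-out FDR per abundance bin, averaged over rotations."""

    bin_edges: Tuple[float, ...]
    fdr: List[float]  # per bin; NaN where no rotation had sites in the bin
    site_counts: List[int]  # pooled over rotations

    def as_frame(self) -> pd.DataFrame:
        lo = self.bin_edges[:-1]
        hi = self.bin_edges[1:]
        return pd.DataFrame(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "fdr": self.fdr,
                "n_sites": self.site_counts,
            }
        )


def _counts_from(profile, metric: str) -> Dict[Site, float]:
    """Accept a ReadCountProfile, a mapping site->count, or a DataFrame."""
    if hasattr(profile, "read_counts"):
        if metric == "reads":
            return profile.read_counts()
        if metric == "ligation_points":
            return profile.ligation_point_counts()
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(profile, pd.DataFrame):
        col = "read_count" if metric == "reads" else "ligation_point_count"
        return {
            (str(r.chrom), int(r.pos)): float(getattr(r, col))
            for r in profile.itertuples()
        }
    return {site: float(c) for site, c in dict(profile).items()}


def normalize_to_max(
    profile,
    metric: str = "reads",
    sites: Optional[Iterable[Site]] = None,
    sample_id: Optional[str] = None,
) -> NormalizedProfile:
    """Express each site's count as a percentage of the top site.

    ``sites`` restricts normalization to a declared site class (e.g.
    spike-in standards are normalized to the most abundant standard,
    separately from genomic sites).  Sites with zero counts are
    dropped; an all-zero profile raises ``ValueError``.
    """
    counts = _counts_from(profile, metric)
    if sites is not None:
        allowed = set(sites)
        counts = {s: c for s, c in counts.items() if s in allowed}
    counts = {s: c for s, c in counts.items() if c > 0}
    if not counts:
        raise ValueError("profile has no sites with positive counts")
    top = max(counts.values())
    sid = sample_id or getattr(profile, "sample_id", "sample")
    return NormalizedProfile(
        sample_id=sid,
        values={s: 100.0 * c / top for s, c in counts.items()},
        metric=metric,
    )


def group_by_abundance(
    norm: NormalizedProfile, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> Dict[Site, int]:
    """Assign each site to a half-open bin (lo, hi]; returns bin indices.

    Edges must be strictly increasing and end at 100.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if edges[-1] != 100.0:
        raise ValueError("bin edges must end at 100")
    out: Dict[Site, int] = {}
    for site, v in norm.values.items():
        # (lo, hi] convention: value equal to an edge falls in the lower bin
        i = int(np.searchsorted(edges, v, side="left")) - 1
        out[site] = max(i, 0)
    return out


def estimate_fdr(
    replicates: Sequence[NormalizedProfile],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> FDRTable:
    """Leave-one-out false discovery rate by abundance bin.

    For each rotation, one replicate is the test set and sites present
    in BOTH remaining replicates form the true-positive set; a test-set
    site absent from the true-positive set is a false positive.  The
    per-bin FDR is false positives / sites in the bin, averaged over
    rotations (bins empty in a rotation are excluded from its average).
    """
    if len(replicates) < 2:
        raise ValueError("at least two replicates are required")
    n_bins = len(bin_edges) - 1
    per_bin_rates: List[List[float]] = [[] for _ in range(n_bins)]
    site_counts = [0] * n_bins
    for i, test in enumerate(replicates):
        others = [r.sites() for j, r in enumerate(replicates) if j != i]
        true_pos = set.intersection(*others)
        bins = group_by_abundance(test, bin_edges)
        in_bin = [0] * n_bins
        fp_in_bin = [0] * n_bins
        for site, b in bins.items():
            in_bin[b] += 1
            if site not in true_pos:
                fp_in_bin[b] += 1
        for b in range(n_bins):
            if in_bin[b] > 0:
                per_bin_rates[b].append(fp_in_bin[b] / in_bin[b])
            site_counts[b] += in_bin[b]
    fdr = [
        float(np.mean(rates)) if rates else float("nan")
        for rates in per_bin_rates
    ]
    return FDRTable(bin_edges=tuple(bin_edges), fdr=fdr, site_counts=site_counts)


def count_ligation_points(
    fragments: Mapping[Site, Iterable[int]]
) -> Dict[Site, int]:
    """Distinct shear positions per site (the ligation-point count)."""
    return {site: len(set(pos)) for site, pos in fragments.items()}


def clonal_expansion_metrics(
    profile,
    annot: Optional[AnnotationSet] = None,
) -> Dict[str, float]:
    """Summary metrics of clonal expansion in one insertion profile.

    ``top5_read_fraction``: percent of all mapped reads assigned to the
    five most abundant sites (all sites when fewer than five).
    ``gene_fraction``: percent of distinct sites inside gene intervals
    (requires ``annot``; NaN otherwise).
    """
    counts = _counts_from(profile, "reads")
    if not counts:
        raise ValueError("profile is empty")
    values = sorted(counts.values(), reverse=True)
    total = sum(values)
    top5 = 100.0 * sum(values[:5]) / total if total > 0 else float("nan")
    gene_fraction = float("nan")
    if annot is not None:
        in_gene = sum(1 for (c, p) in counts if annot.covers(c, p, "gene"))
        gene_fraction = 100.0 * in_gene / len(counts)
    return {"top5_read_fraction": top5, "gene_fraction": gene_fraction}
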