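"""Forward simulator of Sleeping Beauty transposition screens.

Generates every input the analysis modules consume: toy reference
genomes (with isochore-like base-composition heterogeneity so that TA
density varies between windows), transposition events with local
hopping, excision footprints, clonal tumors with tiered site
abundances, spike-in standards at 1.0/0.5/0.125 copies per genome,
replicate LM-PCR read-count profiles, unselected multi-sample insertion
profiles, and footprint sequencing libraries with endogenous-motif
background.

All stochastic functions take an integer ``seed`` and are exactly
reproducible given (seed, parameters).

Default study conditions
------------------------
* spike-in / clone tiers: 1.0, 0.5, 0.125 copies per genome
  (mutations in 100%, 50%, 12.5% of tumor cells);
* local hopping: 6 Mb window, 85% of re-integrations local;
* three LM-PCR replicates per tumor;
* Poisson read-count noise by default, negative binomial when
  ``dispersion > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import (
    FOOTPRINT_VARIANTS,
    GenomicInterval,
    AnnotationSet,
    ReferenceGenome,
    TAIndex,
    build_ta_index,
)

__all__ = [
    "ConcatemerSpec",
    "TranspositionEvent",
    "TumorSim",
    "SpikeInStandard",
    "ReadCountProfile",
    "random_genome",
    "random_annotation",
    "apply_insertion",
    "apply_excision",
    "simulate_transposition",
    "make_clonal_tumor",
    "make_spikein_standards",
    "simulate_replicates",
    "simulate_unselected_profile",
    "simulate_footprint_library",
    "DEFAULT_TIERS",
    "DEFAULT_LOCAL_WINDOW",
    "DEFAULT_P_LOCAL",
]

Site = Tuple[str, int]  # (sequence name, TA position)

DEFAULT_TIERS: Tuple[float, float, float] = (1.0, 0.5, 0.125)
DEFAULT_LOCAL_WINDOW = 6_000_000  # bp
DEFAULT_P_LOCAL = 0.85


@dataclass(frozen=True)
class ConcatemerSpec:
    """Location and copy number of the transposon donor concatemer."""

    chrom: str
    position: int
    copy_number: int = 25
    transposon_length: int = 2200

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(frozen=True)
class TranspositionEvent:
    chrom: str
    target: int  # TA position in the pre-event genome
    kind: str  # "insertion" | "excision-leaving-footprint"
    footprint_variant: Optional[str] = None
    origin: str = "concatemer"  # "concatemer" | "remobilized"

    def __post_init__(self) -> None:
        if self.kind == "excision-leaving-footprint":
            if self.footprint_variant not in FOOTPRINT_VARIANTS:
                raise ValueError("excision events need a footprint variant")
        elif self.footprint_variant is not None:
            raise ValueError("footprint_variant only applies to excision events")


@dataclass
class TumorSim:
    """Ground truth for one simulated tumor.

    ``clone_sites`` maps each clonally expanded insertion site to its
    true relative clonality in (0, 1]; the site at clonality 1.0
    defines the dominant clone.  ``background_sites`` are low-abundance
    passenger insertions that drop in and out of replicate libraries.
    """

    sample_id: str
    clone_sites: Dict[Site, float]
    background_sites: Dict[Site, float] = field(default_factory=dict)
    footprint_events: List[TranspositionEvent] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.clone_sites and not math.isclose(max(self.clone_sites.values()), 1.0):
            raise ValueError("the dominant clone must have clonality 1.0")

    @property
    def all_sites(self) -> Dict[Site, float]:
        merged = dict(self.background_sites)
        merged.update(self.clone_sites)
        return merged


@dataclass(frozen=True)
class SpikeInStandard:
    """A paired-template spike-in plasmid: left- and right-ITR junction
    templates at two genomic loci, physically linked at one tier."""

    standard_id: str
    left_site: Site
    right_site: Site
    tier: float  # copies per genome: 1.0 | 0.5 | 0.125


@dataclass
class ReadCountProfile:
    """One LM-PCR sequencing library of one sample."""

    sample_id: str
    replicate_id: str
    counts: Dict[Site, Tuple[int, int]]  # site -> (reads, ligation points)

    @property
    def total_reads(self) -> int:
        return int(sum(r for r, _ in self.counts.values()))

    def read_counts(self) -> Dict[Site, int]:
        return {s: r for s, (r, _) in self.counts.items()}

    def ligation_point_counts(self) -> Dict[Site, int]:
        return {s: l for s, (_, l) in self.counts.items()}


# ---------------------------------------------------------------------------
# toy genomes and annotation


def random_genome(
    lengths: Mapping[str, int],
    seed: int,
    gc_range: Tuple[float, float] = (0.35, 0.55),
    block_size: int = 20_000,
) -> ReferenceGenome:
    """Random genome with block-wise GC heterogeneity.

    Each ``block_size`` segment draws its own GC content uniformly from
    ``gc_range``, mimicking isochore structure so that TA density varies
    between fixed-width analysis windows — without this, the TA-count
    covariate of the window regression is nearly constant and weakly
    identified.
    """
    rng = np.random.default_rng(seed)
    sequences: Dict[str, str] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name, length in lengths.items():
        chunks: List[np.ndarray] = []
        remaining = length
        while remaining > 0:
            n = min(block_size, remaining)
            gc = rng.uniform(*gc_range)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            chunks.append(rng.choice(bases, size=n, p=p))
            remaining -= n
        sequences[name] = np.concatenate(chunks).tobytes().decode("ascii")
    return ReferenceGenome(sequences)


def random_annotation(
    genome: ReferenceGenome,
    seed: int,
    gene_density: float = 0.4,
    mean_gene_length: int = 8_000,
    exons_per_gene: int = 4,
    exon_length: int = 200,
) -> AnnotationSet:
    """Non-overlapping gene models with exons and explicit introns.

    ``gene_density`` is the approximate fraction of the genome covered
    by genes.  Exons are placed at the gene ends and evenly inside;
    inter-exon gaps are emitted as intron intervals.
    """
    rng = np.random.default_rng(seed)
    intervals: List[GenomicInterval] = []
    gidx = 0
    for chrom, length in genome.lengths.items():
        pos = 0
        while pos < length - mean_gene_length:
            gap = int(rng.exponential(mean_gene_length * (1 - gene_density) / max(gene_density, 1e-9)))
            start = pos + max(gap, 50)
            glen = max(int(rng.normal(mean_gene_length, mean_gene_length / 4)), exon_length * exons_per_gene + 400)
            end = min(start + glen, length)
            if end - start < exon_length * exons_per_gene + 400:
                break
            gidx += 1
            label = f"gene{gidx}"
            intervals.append(GenomicInterval(chrom, start, end, "gene", label))
            # evenly spaced exons; introns fill the gaps
            span = end - start
            step = span // exons_per_gene
            prev_end = start
            for e in range(exons_per_gene):
                es = start + e * step
                ee = es + exon_length
                intervals.append(GenomicInterval(chrom, es, ee, "exon", label))
                if es > prev_end:
                    intervals.append(GenomicInterval(chrom, prev_end, es, "intron", label))
                prev_end = ee
            if prev_end < end:
                intervals.append(GenomicInterval(chrom, prev_end, end, "intron", label))
            pos = end
    return AnnotationSet(intervals, sequence_names=genome.names())


# ---------------------------------------------------------------------------
# integration / excision mechanics


def apply_insertion(sequence: str, ta_pos: int, transposon: str) -> str:
    """Integrate a transposon at a TA dinucleotide.

    Integration duplicates the TA target site, so the product reads
    ``prefix + TA + transposon + TA + suffix`` and is ``len(transposon)
    + 2`` bp longer than the input.
    """
    if sequence[ta_pos : ta_pos + 2] != "TA":
        raise ValueError(f"position {ta_pos} is not a TA dinucleotide")
    return sequence[: ta_pos + 2] + transposon + "TA" + sequence[ta_pos + 2 :]


def apply_excision(
    sequence: str, ta_pos: int, transposon: str, variant: str = "TACAGTA"
) -> str:
    """Excise an integrated transposon, leaving a footprint.

    The cut-and-paste mechanism leaves three ITR-derived bases between
    the duplicated TAs, so the donor locus ends up carrying one of the
    consensus 7-mers (TACAGTA or TACTGTA) in place of the original TA —
    a net gain of five bases over the pre-insertion sequence.
    """
    if variant not in FOOTPRINT_VARIANTS:
        raise ValueError(f"unknown footprint variant {variant!r}")
    occupied = "TA" + transposon + "TA"
    if sequence[ta_pos : ta_pos + len(occupied)] != occupied:
        raise ValueError(f"no integrated transposon found at position {ta_pos}")
    return sequence[:ta_pos] + variant + sequence[ta_pos + len(occupied) :]


# ---------------------------------------------------------------------------
# transposition with local hopping


def simulate_transposition(
    genome: ReferenceGenome,
    concatemer: ConcatemerSpec,
    n_events: int,
    p_local: float = DEFAULT_P_LOCAL,
    local_window: int = DEFAULT_LOCAL_WINDOW,
    seed: int = 0,
    ta_index: Optional[TAIndex] = None,
) -> List[TranspositionEvent]:
    """Draw insertion targets with a local-hopping mixture.

    With probability ``p_local`` the target TA is uniform over TAs
    within ``±local_window`` of the concatemer on its chromosome;
    otherwise uniform over all remaining TAs genome-wide.
    """
    if not 0 <= p_local <= 1:
        raise ValueError("p_local must lie in [0, 1]")
    if local_window <= 0:
        raise ValueError("local_window must be positive")
    index = ta_index if ta_index is not None else build_ta_index(genome)
    lo = concatemer.position - local_window
    hi = concatemer.position + local_window
    local = [
        (concatemer.chrom, int(p))
        for p in index.in_window(concatemer.chrom, lo, hi)
    ]
    local_set = set(local)
    distal = [
        (chrom, int(p))
        for chrom, positions in index.positions.items()
        for p in positions
        if (chrom, int(p)) not in local_set
    ]
    rng = np.random.default_rng(seed)
    events: List[TranspositionEvent] = []
    for _ in range(n_events):
        use_local = rng.random() < p_local
        pool = local if use_local else distal
        if not pool:
            raise ValueError(
                "no TA sites available in the "
                + ("local" if use_local else "distal")
                + " stratum"
            )
        chrom, pos = pool[rng.integers(len(pool))]
        events.append(TranspositionEvent(chrom, pos, "insertion", origin="concatemer"))
    return events


# ---------------------------------------------------------------------------
# clonal tumors, spike-ins, replicate libraries


def _pick_sites(index: TAIndex, n: int, rng: np.random.Generator) -> List[Site]:
    flat = [
        (chrom, int(p)) for chrom, positions in index.positions.items() for p in positions
    ]
    if n > len(flat):
        raise ValueError(f"requested {n} sites but genome has only {len(flat)} TAs")
    idx = rng.choice(len(flat), size=n, replace=False)
    return [flat[i] for i in sorted(idx)]


def make_clonal_tumor(
    ta_index: TAIndex,
    seed: int,
    sample_id: str = "tumor1",
    tier_sizes: Mapping[float, int] = None,
    n_background: int = 200,
    background_clonality: Tuple[float, float] = (2e-5, 6e-4),
) -> TumorSim:
    """A tumor with tiered clonal sites plus low-abundance background.

    Defaults mimic the spike-in design: ten clonally expanded sites
    split across the 1.0 / 0.5 / 0.125 tiers, and a few hundred
    passenger insertions at clonalities low enough that, at typical
    library depth, they surface in some replicates and not others.
    """
    if tier_sizes is None:
        tier_sizes = {1.0: 4, 0.5: 3, 0.125: 3}
    rng = np.random.default_rng(seed)
    n_clones = sum(tier_sizes.values())
    sites = _pick_sites(ta_index, n_clones + n_background, rng)
    clone_sites: Dict[Site, float] = {}
    i = 0
    for tier, size in tier_sizes.items():
        for _ in range(size):
            clone_sites[sites[i]] = tier
            i += 1
    lo, hi = background_clonality
    bg = {
        s: float(c)
        for s, c in zip(
            sites[i:], np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_background))
        )
    }
    return TumorSim(
        sample_id=sample_id,
        clone_sites=clone_sites,
        background_sites=bg,
        seed=seed,
    )


def make_spikein_standards(
    ta_index: TAIndex,
    seed: int,
    n_standards: int = 10,
    tier_split: Sequence[int] = (4, 3, 3),
) -> List[SpikeInStandard]:
    """Ten paired-template standards split across the three tiers."""
    if sum(tier_split) != n_standards:
        raise ValueError("tier_split must sum to n_standards")
    rng = np.random.default_rng(seed)
    sites = _pick_sites(ta_index, 2 * n_standards, rng)
    standards: List[SpikeInStandard] = []
    tiers = [t for t, k in zip(DEFAULT_TIERS, tier_split) for _ in range(k)]
    for i, tier in enumerate(tiers):
        standards.append(
            SpikeInStandard(
                standard_id=f"std{i + 1:02d}",
                left_site=sites[2 * i],
                right_site=sites[2 * i + 1],
                tier=tier,
            )
        )
    return standards


def _draw_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts, or negative binomial (var = mu + dispersion*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def _ligation_points(
    reads: np.ndarray, shear_span: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct shear positions among `reads` fragments.

    Each sequenced fragment ends at a shear point drawn uniformly from
    ``shear_span`` positions near the site; the ligation-point count is
    the number of distinct shear positions, hence always <= reads.
    Computed via the exact expectation-free simulation (multinomial
    occupancy draw).
    """
    out = np.zeros_like(reads)
    for i, n in enumerate(reads):
        if n > 0:
            out[i] = len(np.unique(rng.integers(0, shear_span, size=int(n))))
    return out


def simulate_replicates(
    tumor: TumorSim,
    n_replicates: int = 3,
    depth: int = 30_000,
    dispersion: float = 0.0,
    shear_span: int = 300,
    seed: int = 0,
    extra_sites: Optional[Mapping[Site, float]] = None,
) -> List[ReadCountProfile]:
    """Independent LM-PCR libraries of one tumor.

    Each site's read count is drawn with mean proportional to
    clonality x depth (Poisson, or negative binomial when
    ``dispersion > 0``); ligation points are distinct shear positions,
    capped by the read count.  ``extra_sites`` (e.g. spike-in standard
    templates mapped to their loci) are added to the site pool with the
    given clonalities.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    site_clonality = dict(tumor.all_sites)
    if extra_sites:
        site_clonality.update(extra_sites)
    sites = list(site_clonality)
    clon = np.array([site_clonality[s] for s in sites], dtype=float)
    if clon.sum() <= 0:
        raise ValueError("tumor has no sites with positive clonality")
    means = depth * clon / clon.sum()
    rng = np.random.default_rng(seed)
    profiles: List[ReadCountProfile] = []
    for r in range(n_replicates):
        reads = _draw_counts(means, dispersion, rng)
        lps = _ligation_points(reads, shear_span, rng)
        counts = {
            s: (int(n), int(l))
            for s, n, l in zip(sites, reads, lps)
            if n > 0
        }
        profiles.append(
            ReadCountProfile(
                sample_id=tumor.sample_id,
                replicate_id=f"rep{r + 1}",
                counts=counts,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# unselected multi-sample profiles (bias-scan input)


def simulate_unselected_profile(
    ta_index: TAIndex,
    total_sites: int,
    n_samples: int = 12,
    chrom_rate: Optional[Mapping[str, float]] = None,
    hotspot: Optional[Tuple[str, int, int, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Distinct insertion sites across samples under a per-TA rate model.

    Every TA carries the same baseline detection rate, optionally
    scaled per chromosome (``chrom_rate``) and within one hotspot
    interval (``hotspot = (chrom, start, end, factor)``).  Each sample
    independently detects each TA with probability proportional to its
    rate, calibrated so the expected pooled number of distinct
    (sample, site) records is ``total_sites``.

    Returns a DataFrame with columns ``sample``, ``chrom``, ``pos``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(ta_index.positions)
    weights: Dict[str, np.ndarray] = {}
    wsum = 0.0
    for chrom in chroms:
        w = np.full(len(ta_index.positions[chrom]), float((chrom_rate or {}).get(chrom, 1.0)))
        if hotspot and hotspot[0] == chrom:
            _, s, e, factor = hotspot
            pos = ta_index.positions[chrom]
            w[(pos >= s) & (pos < e)] *= factor
        weights[chrom] = w
        wsum += w.sum()
    p_scale = total_sites / (n_samples * wsum)
    rows = []
    for i in range(n_samples):
        sample = f"s{i + 1:03d}"
        for chrom in chroms:
            p = np.minimum(weights[chrom] * p_scale, 1.0)
            hit = rng.random(len(p)) < p
            for pos in ta_index.positions[chrom][hit]:
                rows.append((sample, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos"])


# ---------------------------------------------------------------------------
# footprint sequencing libraries


def simulate_footprint_library(
    genome: ReferenceGenome,
    footprint_sites: Mapping[str, Iterable[Site]],
    insertion_sites: Mapping[str, Iterable[Site]],
    depth: float = 200.0,
    seed: int = 0,
    normal_id: str = "normal",
    depth_by_class: Optional[Mapping[str, float]] = None,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample footprint-library site tables plus a truth table.

    The footprint library chemistry amplifies three classes of loci:
    true excision footprints, endogenous TACWGTA occurrences (present
    in the matched normal as well), and the HpyCH4III sites created at
    every surviving ITR/genome junction.  Plus- and minus-strand reads
    at each locus are drawn independently as Poisson(depth / 2);
    ``depth_by_class`` overrides the mean per truth class (e.g.
    shallower coverage at subclonal ITR junctions).

    Returns ``(tables, truth)`` where ``tables[sample]`` has columns
    ``chrom, pos, plus_reads, minus_reads`` (including the normal
    sample, which carries only the endogenous loci) and ``truth`` has
    columns ``sample, chrom, pos, truth_class`` with class in
    {footprint, endogenous, itr_junction}.
    """
    from .genome import FOOTPRINT_MOTIF, scan_motif

    rng = np.random.default_rng(seed)
    endogenous = [
        (h.chrom, h.start)
        for h in scan_motif(genome, FOOTPRINT_MOTIF, both_strands=False)
    ]
    tables: Dict[str, pd.DataFrame] = {}
    truth_rows: List[Tuple[str, str, int, str]] = []

    def _emit(sample: str, loci: List[Tuple[str, int, str]]) -> pd.DataFrame:
        rows = []
        for chrom, pos, klass in loci:
            mean = (depth_by_class or {}).get(klass, depth)
            plus = int(rng.poisson(mean / 2))
            minus = int(rng.poisson(mean / 2))
            rows.append((chrom, pos, plus, minus))
            truth_rows.append((sample, chrom, pos, klass))
        return pd.DataFrame(rows, columns=["chrom", "pos", "plus_reads", "minus_reads"])

    tables[normal_id] = _emit(normal_id, [(c, p, "endogenous") for c, p in endogenous])
    for sample in footprint_sites:
        loci = [(c, p, "endogenous") for c, p in endogenous]
        loci += [(c, p, "footprint") for c, p in footprint_sites[sample]]
        loci += [(c, p, "itr_junction") for c, p in insertion_sites.get(sample, [])]
        tables[sample] = _emit(sample, loci)
    truth = pd.DataFrame(truth_rows, columns=["sample", "chrom", "pos", "truth_class"])
    return tables, truth
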