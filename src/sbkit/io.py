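"""Shared I/O: FASTA, BED, TSV site tables, coordinate conversion,
run configuration and manifests.

All on-disk coordinates are 1-based inclusive (the convention of the
report tables); everything in memory is 0-based half-open.  The
converters here are the only place that translation happens.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotationSet, GenomicInterval, MotifHit, ReferenceGenome

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_bed",
    "read_site_table",
    "write_site_table",
    "to_one_based",
    "from_one_based",
    "format_region",
    "parse_region",
    "RunConfig",
    "load_config",
    "write_manifest",
    "SITE_TABLE_COLUMNS",
]

SITE_TABLE_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "strand",
    "read_count",
    "ligation_point_count",
]


# ---------------------------------------------------------------------------
# coordinates


def to_one_based(start: int, end: int) -> Tuple[int, int]:
    """Internal 0-based half-open [start, end) -> reported 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> Tuple[int, int]:
    """Reported 1-based inclusive -> internal 0-based half-open."""
    return first - 1, last


def format_region(chrom: str, start: int, end: int) -> str:
    """Render an internal interval as e.g. ``chr11:3,180,001-3,200,000``."""
    first, last = to_one_based(start, end)
    return f"{chrom}:{first:,}-{last:,}"


def parse_region(region: str) -> Tuple[str, int, int]:
    """Inverse of :func:`format_region`."""
    chrom, span = region.rsplit(":", 1)
    first, last = span.replace(",", "").split("-")
    start, end = from_one_based(int(first), int(last))
    return chrom, start, end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> ReferenceGenome:
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation (BED-like TSV: chrom, start, end, feature, label; 0-based half-open)


def read_annotation(path, sequence_names: Optional[Iterable[str]] = None) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "feature", "label"],
                     dtype={"chrom": str, "feature": str, "label": str})
    intervals = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.feature,
                        "" if pd.isna(r.label) else str(r.label))
        for r in df.itertuples()
    ]
    return AnnotationSet(intervals, sequence_names=sequence_names)


def write_annotation(annot: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for iv in annot.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.feature}\t{iv.label}\n")


def write_bed(
    rows: Iterable, path, name_of=None
) -> None:
    """Write MotifHit objects or (chrom, start, end[, name[, strand]])
    tuples as BED (0-based half-open, the BED convention)."""
    with open(path, "w") as fh:
        for row in rows:
            if isinstance(row, MotifHit):
                name = name_of(row) if name_of else row.motif
                end = row.start + len(row.motif)
                fh.write(
                    f"{row.chrom}\t{row.start}\t{end}\t{name}\t0\t{row.strand}\n"
                )
            else:
                fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# site tables


def read_site_table(path) -> pd.DataFrame:
    """Read a TSV site table (header required, 1-based positions).

    Duplicate (sample, chrom, pos, strand) rows are summed with a
    warning.  Malformed or negative-count rows raise ``ValueError``
    naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "strand": str})
    missing = [c for c in ("sample", "chrom", "pos", "strand", "read_count") if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing columns: {missing}")
    if "ligation_point_count" not in df.columns:
        df["ligation_point_count"] = 0
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        try:
            pos = int(row.pos)
            rc = int(row.read_count)
            lc = int(row.ligation_point_count)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: malformed row at line {i}") from None
        if pos < 1:
            raise ValueError(f"{path}: non-positive position at line {i}")
        if rc < 0 or lc < 0:
            raise ValueError(f"{path}: negative count at line {i}")
        if lc > rc:
            raise ValueError(
                f"{path}: ligation points exceed read count at line {i}"
            )
        if row.strand not in ("+", "-"):
            raise ValueError(f"{path}: invalid strand at line {i}")
    key = ["sample", "chrom", "pos", "strand"]
    if df.duplicated(subset=key).any():
        warnings.warn(f"{path}: duplicate site rows summed", stacklevel=2)
        df = df.groupby(key, as_index=False)[["read_count", "ligation_point_count"]].sum()
    # internal 0-based position
    df["pos"] = df["pos"].astype(int) - 1
    return df[SITE_TABLE_COLUMNS]


def write_site_table(df: pd.DataFrame, path) -> None:
    """Write a site table, converting positions back to 1-based."""
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    cols = [c for c in SITE_TABLE_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration and manifests


_KNOWN_KEYS = {
    "paths": {"genome", "annotation", "site_tables", "output_dir", "repeats"},
    "params": {
        "window_width",
        "bin_edges",
        "confidence_percentile",
        "p_local",
        "local_window",
        "alpha",
        "seed",
        "depth",
        "n_replicates",
        "dispersion",
        "score_min",
        "alt_mismatch_limit",
        "lengths",
    },
}


@dataclass
class RunConfig:
    """Structured run configuration; unknown keys are rejected at load."""

    paths: Dict[str, object] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)
    version: str = ""

    def seed(self, default: int = 0) -> int:
        return int(self.params.get("seed", default))


def load_config(path, check_paths: bool = True) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"paths", "params", "version"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _KNOWN_KEYS.items():
        extra = set(raw.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
    cfg = RunConfig(
        paths=raw.get("paths", {}),
        params=raw.get("params", {}),
        version=str(raw.get("version", "")),
    )
    if check_paths:
        for key, p in cfg.paths.items():
            if key == "output_dir":
                continue
            for one in p if isinstance(p, list) else [p]:
                if not Path(one).exists():
                    raise FileNotFoundError(f"config path {key!r}: {one} does not exist")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    inputs: Mapping[str, object] = (),
    params: Mapping[str, object] = (),
    outputs: Iterable[str] = (),
) -> None:
    """Record input checksums, parameters, and tool version."""
    from . import __version__

    manifest = {
        "tool": "sbkit",
        "version": __version__,
        "inputs": {
            str(k): {"path": str(v), "sha256": _sha256(v)}
            for k, v in dict(inputs).items()
            if v is not None and Path(str(v)).exists()
        },
        "params": {str(k): v for k, v in dict(params).items()},
        "outputs": [str(o) for o in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
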