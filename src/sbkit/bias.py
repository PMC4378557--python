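"""Detection-bias scan over fixed-width genomic windows.

The genome is tiled into non-overlapping windows (20 kb default) and
the number of distinct insertion sites observed in each window is
compared to the expectation from a Poisson log-linear model — the
Poisson Regression Insertion Model (PRIM) — with log TA count as a
covariate and chromosome as a factor.  Per-window enrichment p-values
are exact Poisson upper tails at the fitted mean, Bonferroni-corrected
over the tested windows.  Windows are additionally flagged as lying on
a concatemer-bearing (local-hopping) chromosome, within the local
window of a concatemer, or overlapping annotated repeats.

Sequencing depth plays no role here: only distinct sites per sample
are counted, deduplicated before pooling across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import AnnotationSet, ReferenceGenome, TAIndex, build_ta_index
from .simulate import ConcatemerSpec

__all__ = [
    "PRIMFit",
    "partition_windows",
    "fit_prim",
    "window_pvalues",
    "flag_windows",
    "enriched_windows",
    "DEFAULT_WINDOW_WIDTH",
]

DEFAULT_WINDOW_WIDTH = 20_000

#: Window-table columns produced by the scan.  ``start``/``end`` are
#: 0-based half-open; report writers render 1-based inclusive strings.
WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "ta_count",
    "observed_sites",
    "expected_sites",
    "p_raw",
    "p_bonferroni",
]


@dataclass
class PRIMFit:
    """Fitted Poisson regression insertion model."""

    params: pd.Series
    total_insertions: int
    n_tested: int
    result: object  # statsmodels GLMResults

    @property
    def log_ta_coefficient(self) -> float:
        return float(self.params["log_ta"])

    def chromosome_effect(self, chrom: str) -> float:
        key = f"chrom[T.{chrom}]"
        return float(self.params[key]) if key in self.params.index else 0.0


def partition_windows(
    genome: ReferenceGenome,
    width: int = DEFAULT_WINDOW_WIDTH,
    ta_index: Optional[TAIndex] = None,
) -> pd.DataFrame:
    """Tile each sequence into non-overlapping windows with TA counts.

    The final partial window of each sequence is retained.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    index = ta_index if ta_index is not None else build_ta_index(genome)
    rows = []
    for chrom, length in genome.lengths.items():
        for start in range(0, length, width):
            end = min(start + width, length)
            rows.append((chrom, start, end, index.count_in(chrom, start, end)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ta_count"])
    df["observed_sites"] = 0
    df["expected_sites"] = np.nan
    df["p_raw"] = np.nan
    df["p_bonferroni"] = np.nan
    return df


def _count_sites_per_window(
    windows: pd.DataFrame, sites: pd.DataFrame
) -> np.ndarray:
    """Distinct (sample, chrom, pos) records per window.

    Sites at the same TA in the same sample (e.g. both ITR
    orientations) collapse to one; the same TA in different samples
    counts once per sample.
    """
    cols = [c for c in ("sample", "chrom", "pos") if c in sites.columns]
    if "sample" not in cols:
        sites = sites.assign(sample="pooled")
    dedup = sites.drop_duplicates(subset=["sample", "chrom", "pos"])
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, group in dedup.groupby("chrom"):
        mask = windows["chrom"] == chrom
        if not mask.any():
            continue
        starts = windows.loc[mask, "start"].to_numpy()
        ends = windows.loc[mask, "end"].to_numpy()
        pos = np.sort(group["pos"].to_numpy())
        counts[np.flatnonzero(mask)] = np.searchsorted(pos, ends) - np.searchsorted(
            pos, starts
        )
    return counts


def fit_prim(
    windows: pd.DataFrame,
    sites: pd.DataFrame,
) -> Tuple[pd.DataFrame, PRIMFit]:
    """Fit the PRIM and fill observed/expected site counts per window.

    Windows with ``ta_count == 0`` cannot receive insertions and are
    excluded from the fit (they are reported with ``p_raw = 1``).  The
    chromosome factor is dropped automatically when only one
    chromosome is present.

    Returns the updated window table and the fit.
    """
    windows = windows.copy()
    windows["observed_sites"] = _count_sites_per_window(windows, sites)
    tested = windows["ta_count"] > 0
    if int(windows.loc[tested, "observed_sites"].sum()) == 0:
        raise ValueError("degenerate design: no insertion sites in any window")
    sub = windows.loc[tested]
    X = pd.DataFrame({"log_ta": np.log(sub["ta_count"].to_numpy(dtype=float))})
    if sub["chrom"].nunique() >= 2:
        dummies = pd.get_dummies(sub["chrom"], prefix="chrom[T.", prefix_sep="", dtype=float)
        dummies.columns = [c + "]" for c in dummies.columns]
        # first level is the reference
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    X = sm.add_constant(X)
    model = sm.GLM(sub["observed_sites"].to_numpy(), X, family=sm.families.Poisson())
    result = model.fit()
    mu = np.asarray(result.mu)
    windows.loc[tested, "expected_sites"] = mu
    fit = PRIMFit(
        params=result.params,
        total_insertions=int(windows["observed_sites"].sum()),
        n_tested=int(tested.sum()),
        result=result,
    )
    return windows, fit


def window_pvalues(windows: pd.DataFrame) -> pd.DataFrame:
    """Exact Poisson upper-tail p-values with Bonferroni correction.

    ``p_raw = P(X >= observed | mu)`` for tested windows; windows with
    no TA sites get ``p_raw = 1`` and are excluded from the Bonferroni
    family.
    """
    windows = windows.copy()
    tested = windows["expected_sites"].notna()
    n_tested = int(tested.sum())
    mu = windows.loc[tested, "expected_sites"].to_numpy(dtype=float)
    obs = windows.loc[tested, "observed_sites"].to_numpy(dtype=float)
    p_raw = stats.poisson.sf(obs - 1, mu)  # P(X >= obs)
    windows.loc[tested, "p_raw"] = p_raw
    windows.loc[~tested, "p_raw"] = 1.0
    windows["p_bonferroni"] = 1.0
    windows.loc[tested, "p_bonferroni"] = np.minimum(p_raw * n_tested, 1.0)
    return windows


def flag_windows(
    windows: pd.DataFrame,
    concatemers: Sequence[ConcatemerSpec] = (),
    local_window: int = 6_000_000,
    repeats: Optional[AnnotationSet] = None,
) -> pd.DataFrame:
    """Flag windows by local-hopping proximity and repeat overlap.

    ``local_chromosome``: the window's sequence hosts a concatemer.
    ``within_local_window``: additionally within ``±local_window`` of
    one (interval overlap with the window, half-open).
    ``repeat_overlap``: at least one annotated repeat interval
    intersects the window.
    """
    windows = windows.copy()
    local_chroms = {c.chrom for c in concatemers}
    windows["local_chromosome"] = windows["chrom"].isin(local_chroms)
    within = np.zeros(len(windows), dtype=bool)
    for c in concatemers:
        lo, hi = c.position - local_window, c.position + local_window
        within |= (
            (windows["chrom"] == c.chrom)
            & (windows["start"] < hi)
            & (windows["end"] > lo)
        ).to_numpy()
    windows["within_local_window"] = within
    if repeats is not None:
        windows["repeat_overlap"] = [
            bool(repeats.overlapping(r.chrom, r.start, r.end, "repeat"))
            for r in windows.itertuples()
        ]
    else:
        windows["repeat_overlap"] = False
    return windows


def enriched_windows(
    windows: pd.DataFrame, alpha: float = 0.05, exclude_local: bool = False
) -> pd.DataFrame:
    """Windows with Bonferroni-corrected p below ``alpha``; optionally
    restricted to non-local chromosomes."""
    mask = windows["p_bonferroni"] < alpha
    if exclude_local and "local_chromosome" in windows.columns:
        mask &= ~windows["local_chromosome"]
    return windows.loc[mask].sort_values("p_raw").reset_index(drop=True)
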