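"""Genomic-interval peak-density analysis around centromeres.

Starting from called peak intervals (BED-like, 0-based half-open), this
module builds replicate-consensus peak sets, computes peaks-per-Mb densities
for labeled region classes (active alpha-satellite HOR arrays, centromere
haplotypes, their 2 Mb flanks, random non-centromeric controls), fragment
midpoint proportions per region class, and pairwise peak-overlap fractions.
Peak calling and read alignment are upstream of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED_COLUMNS = ["chrom", "start", "end"]


def _as_frame(intervals) -> pd.DataFrame:
    df = pd.DataFrame(intervals)
    if df.empty:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table missing columns {missing}")
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError("intervals must satisfy start < end")
    if (df["start"] < 0).any():
        raise ValueError("intervals must satisfy start >= 0")
    out = df[BED_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (first three columns; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    df.columns = BED_COLUMNS
    return _as_frame(df)


def write_bed(df: pd.DataFrame, path) -> None:
    _as_frame(df).to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping or touching intervals per chromosome."""
    df = _as_frame(df)
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


@dataclass
class RegionSet:
    """Labeled genomic intervals; intervals are normalized (merged) so the
    total length is well defined."""

    label: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6

    def tree_by_chrom(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"])
            )
        return trees


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in _as_frame(df).groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
    return trees


def consensus_peaks(replicates: list[pd.DataFrame], min_support: int = 2) -> pd.DataFrame:
    """Replicate-consensus peak loci.

    All replicate peaks are union-merged into candidate loci; a locus is kept
    when peaks from at least ``min_support`` distinct replicates overlap it.
    min_support=1 returns the merged union; min_support=len(replicates) the
    loci supported by every replicate.
    """
    reps = [_as_frame(r) for r in replicates]
    if not reps:
        return pd.DataFrame(columns=BED_COLUMNS)
    if not 1 <= min_support <= len(reps):
        raise ValueError("min_support must be between 1 and the number of replicates")
    union = merge_intervals(pd.concat(reps, ignore_index=True))
    trees = [_trees(r) for r in reps]
    keep = []
    for chrom, s, e in union.itertuples(index=False):
        support = sum(1 for t in trees if chrom in t and t[chrom].overlap(s, e))
        if support >= min_support:
            keep.append((chrom, s, e))
    return pd.DataFrame(keep, columns=BED_COLUMNS)


@dataclass
class PeakDensityRecord:
    label: str
    chrom: str  # specific chromosome or "all"
    peak_count: int
    region_mb: float
    density_per_mb: float
    log2_density: float  # NaN where the count is zero


def _midpoints(df: pd.DataFrame) -> pd.DataFrame:
    df = _as_frame(df)
    mid = (df["start"] + df["end"]) // 2
    return pd.DataFrame({"chrom": df["chrom"], "pos": mid})


def density_per_region(
    peaks: pd.DataFrame,
    region_sets: list[RegionSet],
    assignment: str = "midpoint",
    per_chromosome: bool = False,
) -> list[PeakDensityRecord]:
    """Peaks-per-Mb for each region class.

    assignment="midpoint" (default) counts a peak in a region iff its
    midpoint lies inside, which makes counts additive over a genome
    partition; "any-overlap" counts any 1 bp overlap.  log2 density is NaN
    for empty regions (no pseudocounts).
    """
    if assignment not in ("midpoint", "any-overlap"):
        raise ValueError("assignment must be 'midpoint' or 'any-overlap'")
    peaks = _as_frame(peaks)
    records: list[PeakDensityRecord] = []
    for rs in region_sets:
        trees = rs.tree_by_chrom()
        if assignment == "midpoint":
            mask = [
                chrom in trees and bool(trees[chrom][(s + e) // 2])
                for chrom, s, e in peaks.itertuples(index=False)
            ]
        else:
            mask = [
                chrom in trees and bool(trees[chrom].overlap(s, e))
                for chrom, s, e in peaks.itertuples(index=False)
            ]
        hits = peaks[mask] if len(peaks) else peaks

        def _record(label, chrom, count, mb) -> PeakDensityRecord:
            dens = count / mb if mb > 0 else math.nan
            l2 = math.log2(dens) if (mb > 0 and count > 0) else math.nan
            return PeakDensityRecord(label, chrom, int(count), mb, dens, l2)

        if per_chromosome:
            lengths = (
                rs.intervals.assign(bp=lambda d: d["end"] - d["start"])
                .groupby("chrom")["bp"].sum()
            )
            counts = hits.groupby("chrom").size() if len(hits) else pd.Series(dtype=int)
            for chrom, bp in lengths.items():
                records.append(
                    _record(rs.label, chrom, int(counts.get(chrom, 0)), bp / 1e6)
                )
        records.append(_record(rs.label, "all", len(hits), rs.total_mb))
    return records


def density_table(records: list[PeakDensityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def read_proportions(
    fragments: pd.DataFrame, region_sets: list[RegionSet]
) -> pd.Series:
    """Fraction of fragments whose midpoint falls in each region class.

    Over disjoint exhaustive classes the proportions sum to 1; overlapping
    classes are each scored independently.
    """
    frags = _as_frame(fragments)
    if frags.empty:
        raise ValueError("read_proportions requires at least one fragment")
    mids = _midpoints(frags)
    out = {}
    for rs in region_sets:
        trees = rs.tree_by_chrom()
        n_in = sum(
            1
            for chrom, pos in mids.itertuples(index=False)
            if chrom in trees and trees[chrom][pos]
        )
        out[rs.label] = n_in / len(mids)
    return pd.Series(out, name="proportion")


def sample_random_regions(
    chrom_sizes: dict[str, int] | pd.DataFrame,
    exclusion: RegionSet | pd.DataFrame | None = None,
    n: int = 100,
    length_bp: int = 2_000_000,
    seed: int = 0,
    max_tries_per_region: int = 10_000,
    label: str = "nonCen",
) -> RegionSet:
    """n random fixed-length regions, uniform over all allowed start
    positions across the genome, rejecting any overlap with the exclusion
    set.  Deterministic under the seed."""
    if isinstance(chrom_sizes, pd.DataFrame):
        chrom_sizes = dict(zip(chrom_sizes.iloc[:, 0], chrom_sizes.iloc[:, 1]))
    chroms = [(c, int(L)) for c, L in sorted(chrom_sizes.items()) if int(L) >= length_bp]
    if not chroms:
        raise ValueError("no chromosome can accommodate the requested length")
    ex_trees: dict[str, IntervalTree] = {}
    if exclusion is not None:
        ex_df = exclusion.intervals if isinstance(exclusion, RegionSet) else exclusion
        ex_trees = _trees(ex_df)
    weights = np.array([L - length_bp + 1 for _, L in chroms], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        for _try in range(max_tries_per_region):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom, L = chroms[ci]
            start = int(rng.integers(0, L - length_bp + 1))
            end = start + length_bp
            if chrom in ex_trees and ex_trees[chrom].overlap(start, end):
                continue
            rows.append((chrom, start, end))
            break
        else:
            raise RuntimeError(
                "could not place a random region outside the exclusion set"
            )
    # keep raw sampled intervals (RegionSet merges, which is fine for density)
    return RegionSet(label=label, intervals=pd.DataFrame(rows, columns=BED_COLUMNS))


def overlap_fraction(query: pd.DataFrame, subject: pd.DataFrame) -> float:
    """Fraction of query intervals overlapped (>= 1 bp) by any subject
    interval."""
    q = _as_frame(query)
    if q.empty:
        raise ValueError("query peak set is empty")
    trees = _trees(subject)
    n_hit = sum(
        1
        for chrom, s, e in q.itertuples(index=False)
        if chrom in trees and trees[chrom].overlap(s, e)
    )
    return n_hit / len(q)
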