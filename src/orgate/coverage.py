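"""Stranded per-base coverage and the relative-coverage statistic.

Readthrough transcription past a gene's polyadenylation site leaves reads in
the intergenic interval downstream; pervasive antisense transcription leaves
reads on the non-coding strand. Both are quantified as *relative coverage*:
the mean depth over a feature divided by the mean sense-strand depth over the
upstream gene's exons in the same pair, which cancels expression-level
differences between gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from orgate.annotation import GenePair, Interval

logger = logging.getLogger(__name__)

FEATURES = (
    "upstream_exons",
    "upstream_introns",
    "downstream_exons",
    "downstream_introns",
    "intergenic",
)


class StrandedCoverageTrack:
    """Dense per-base read depth, one array per (chromosome, strand)."""

    def __init__(self, chrom_lengths: dict[str, int], dtype=np.float64):
        self.chrom_lengths = dict(chrom_lengths)
        self.depth = {
            chrom: {s: np.zeros(length, dtype=dtype) for s in "+-"}
            for chrom, length in self.chrom_lengths.items()
        }

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        chrom, strand = key
        return self.depth[chrom][strand]

    def add_interval(self, chrom: str, strand: str, start: int, end: int, value: float) -> None:
        self.depth[chrom][strand][start:end] += value

    def scaled(self, c: float) -> "StrandedCoverageTrack":
        out = StrandedCoverageTrack(self.chrom_lengths)
        for chrom in self.depth:
            for s in "+-":
                out.depth[chrom][s] = self.depth[chrom][s] * c
        return out


def read_bedgraph_pair(
    plus_path: str, minus_path: str, chrom_lengths: dict[str, int]
) -> StrandedCoverageTrack:
    """Load one bedGraph per strand into dense arrays (uncovered bases = 0).

    Intervals are half-open as in the format; records on chromosomes absent
    from ``chrom_lengths`` are skipped with a warning, and overlapping
    self-contradictory records resolve last-wins.
    """
    track = StrandedCoverageTrack(chrom_lengths)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
                skip_blank_lines=True,
            )
        except pd.errors.EmptyDataError:
            continue
        df = df[~df["chrom"].str.startswith(("track", "browser"))]
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_lengths:
                logger.warning("bedGraph %s: unknown chromosome %s skipped", path, chrom)
                continue
            arr = track.depth[chrom][strand]
            starts = sub["start"].to_numpy(int)
            ends = sub["end"].to_numpy(int)
            vals = sub["value"].to_numpy(float)
            if np.any(starts < 0) or np.any(ends > len(arr)):
                raise ValueError(f"bedGraph {path}: interval outside {chrom} bounds")
            prev_end = -1
            for s, e, v in zip(starts, ends, vals):
                if s < prev_end:
                    logger.warning("bedGraph %s: overlapping records at %s:%d; last wins", path, chrom, s)
                arr[s:e] = v
                prev_end = max(prev_end, e)
    return track


def write_bedgraph_pair(
    track: StrandedCoverageTrack, plus_path: str, minus_path: str
) -> None:
    """Write dense arrays back to run-length-encoded bedGraph (zeros omitted)."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for chrom in sorted(track.chrom_lengths):
                arr = track.depth[chrom][strand]
                if not len(arr):
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    if arr[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def mean_region_coverage(
    track: StrandedCoverageTrack, intervals: list[Interval], chrom: str, strand: str
) -> float:
    """Base-weighted mean depth over the union of intervals."""
    arr = track.depth[chrom][strand]
    total, bases = 0.0, 0
    for s, e in _union(intervals):
        total += float(arr[s:e].sum())
        bases += e - s
    if bases == 0:
        raise ValueError("zero-length interval union")
    return total / bases


def _union(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def introns_of(gene) -> list[Interval]:
    exons = sorted(gene.exons)
    return [
        (exons[i - 1][1], exons[i][0])
        for i in range(1, len(exons))
        if exons[i][0] > exons[i - 1][1]
    ]


@dataclass
class RelativeCoverageRecord:
    pair_id: str
    pair_class: str
    feature: str
    orientation: str  # {'sense', 'antisense'}
    mean_cov: float
    rel_cov: float | None  # None when the normalizer is zero


def pair_relative_coverage(
    pair: GenePair,
    track: StrandedCoverageTrack,
    orientations: tuple[str, ...] = ("sense", "antisense"),
) -> list[RelativeCoverageRecord]:
    """Relative coverage for the five pair features in each orientation.

    The normalizer is the sense-strand mean over the upstream gene's exons;
    when it is zero every record of the pair has ``rel_cov=None`` and is
    excluded from downstream statistics.
    """
    chrom = pair.chrom
    sense = pair.strand
    anti = "-" if sense == "+" else "+"
    regions = {
        "upstream_exons": pair.upstream.exons,
        "upstream_introns": introns_of(pair.upstream),
        "downstream_exons": pair.downstream.exons,
        "downstream_introns": introns_of(pair.downstream),
        "intergenic": [pair.intergenic] if pair.intergenic_length > 0 else [],
    }
    norm = mean_region_coverage(track, pair.upstream.exons, chrom, sense)
    if norm == 0:
        logger.warning("pair %s: zero upstream exon coverage; rel_cov undefined", pair.pair_id)
    out = []
    for orientation in orientations:
        strand = sense if orientation == "sense" else anti
        for feature, ivs in regions.items():
            if not ivs:
                continue
            mean = mean_region_coverage(track, ivs, chrom, strand)
            out.append(
                RelativeCoverageRecord(
                    pair_id=pair.pair_id,
                    pair_class=pair.pair_class,
                    feature=feature,
                    orientation=orientation,
                    mean_cov=mean,
                    rel_cov=(mean / norm) if norm > 0 else None,
                )
            )
    return out


def records_frame(records: list[RelativeCoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def compare_groups(
    or_records: list[RelativeCoverageRecord],
    nonor_records: list[RelativeCoverageRecord],
    features: tuple[str, ...] = FEATURES,
    orientation: str = "sense",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature, BH-adjusted across features.

    Records with an undefined normalizer are dropped; features with fewer
    than two defined values in either group are skipped with a warning.
    """

    def values(recs, feature):
        return [
            r.rel_cov
            for r in recs
            if r.feature == feature and r.orientation == orientation and r.rel_cov is not None
        ]

    rows = []
    for feature in features:
        a, b = values(or_records, feature), values(nonor_records, feature)
        if len(a) < 2 or len(b) < 2:
            logger.warning("feature %s skipped: fewer than 2 defined values per group", feature)
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"feature": feature, "statistic": res.statistic, "p_raw": res.pvalue})
    df = pd.DataFrame(rows)
    if len(df) > 1:
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    elif len(df) == 1:
        df["p_adj"] = df["p_raw"]
    return df
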