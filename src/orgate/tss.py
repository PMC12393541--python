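"""Promoter-window assignment of capped-small-RNA start sites.

Capped small-RNA sequencing marks transcription start sites at single-base
resolution. Each gene gets a fixed window upstream of its anchor (first CDS
for ORs, whose UTR annotations are unreliable; annotated TSS otherwise).
Reads on the gene's strand inside that window are *sense* initiation, reads
on the opposite strand are *antisense* initiation from the same promoter
region; a promoter is bidirectional when both strands reach a configurable
read minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orgate.annotation import GeneModel

logger = logging.getLogger(__name__)


class TssTrack:
    """Sparse per-strand 5'-end read counts: chrom -> strand -> {pos: count}."""

    def __init__(self, chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self.counts: dict[str, dict[str, dict[int, int]]] = {
            chrom: {"+": {}, "-": {}} for chrom in chrom_lengths
        }

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if count < 0:
            raise ValueError("TSS counts must be non-negative")
        d = self.counts[chrom][strand]
        d[pos] = d.get(pos, 0) + count

    def total(self, chrom: str) -> int:
        return sum(sum(d.values()) for d in self.counts[chrom].values())

    def in_window(self, chrom: str, strand: str, start: int, end: int) -> list[tuple[int, int]]:
        """(position, count) pairs with start <= position < end."""
        d = self.counts[chrom][strand]
        return sorted((p, c) for p, c in d.items() if start <= p < end)


def read_tss_bedgraph_pair(
    plus_path: str, minus_path: str, chrom_lengths: dict[str, int]
) -> TssTrack:
    """Stranded bedGraph of 5'-end counts -> sparse track (integer counts)."""
    track = TssTrack(chrom_lengths)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        try:
            df = pd.read_csv(
                path, sep="\t", comment="#", header=None,
                names=["chrom", "start", "end", "value"], dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            continue
        for row in df.itertuples(index=False):
            if row.chrom not in chrom_lengths:
                logger.warning("TSS bedGraph %s: unknown chromosome %s skipped", path, row.chrom)
                continue
            for pos in range(int(row.start), int(row.end)):
                track.add(row.chrom, strand, pos, int(round(row.value)))
    return track


def write_tss_bedgraph_pair(track: TssTrack, plus_path: str, minus_path: str) -> None:
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for chrom in sorted(track.counts):
                for pos, count in sorted(track.counts[chrom][strand].items()):
                    if count:
                        fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")


@dataclass
class PromoterWindowResult:
    gene_id: str
    window: tuple[int, int]
    truncated: bool
    sense_count: int
    antisense_count: int
    sense_positions: list[int] = field(default_factory=list)  # distance-to-anchor, bp
    antisense_positions: list[int] = field(default_factory=list)
    bidirectional: bool = False


def window_assign(
    track: TssTrack,
    genes: list[GeneModel],
    anchors: dict[str, int],
    window_bp: int = 1000,
    min_reads: int = 1,
) -> list[PromoterWindowResult]:
    """Assign start-site reads to each gene's upstream promoter window.

    The window is the ``window_bp`` bases upstream of the anchor on the
    gene's strand; both strands are searched over the same genomic interval.
    Distances run from the anchor toward upstream, so a read at the anchor
    has distance 0. Windows truncated at the chromosome start are shortened
    and flagged. A read may fall in several genes' windows (overlapping
    promoters); every assignment is kept.
    """
    out = []
    for gene in genes:
        anchor = anchors[gene.gene_id]
        if gene.strand == "+":
            lo, hi = anchor - window_bp + 1, anchor + 1
        else:
            lo, hi = anchor, anchor + window_bp
        truncated = lo < 0
        lo = max(lo, 0)
        hi = min(hi, track.chrom_lengths[gene.chrom])
        anti = "-" if gene.strand == "+" else "+"
        res = PromoterWindowResult(
            gene_id=gene.gene_id, window=(lo, hi), truncated=truncated,
            sense_count=0, antisense_count=0,
        )
        for strand, positions, attr in (
            (gene.strand, res.sense_positions, "sense_count"),
            (anti, res.antisense_positions, "antisense_count"),
        ):
            for pos, count in track.in_window(gene.chrom, strand, lo, hi):
                dist = anchor - pos if gene.strand == "+" else pos - anchor
                positions.extend([dist] * count)
                setattr(res, attr, getattr(res, attr) + count)
        res.bidirectional = res.sense_count >= min_reads and res.antisense_count >= min_reads
        out.append(res)
    return out


def bidirectional_fraction(results: list[PromoterWindowResult]) -> float:
    """Fraction of promoter windows with reads on both strands."""
    if not results:
        raise ValueError("no promoter windows")
    return sum(r.bidirectional for r in results) / len(results)


def peak_offset_histogram(
    results: list[PromoterWindowResult],
    orientation: str = "sense",
    bin_width: int = 50,
    window_bp: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Read-weighted histogram of anchor distances; returns (counts, edges)."""
    attr = "sense_positions" if orientation == "sense" else "antisense_positions"
    dists = np.concatenate([np.asarray(getattr(r, attr), dtype=float) for r in results]) \
        if results else np.empty(0)
    edges = np.arange(0, window_bp + bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return counts, edges


def median_offset(results: list[PromoterWindowResult], orientation: str) -> float:
    """Read-weighted median distance from anchor for one orientation."""
    attr = "sense_positions" if orientation == "sense" else "antisense_positions"
    dists = [d for r in results for d in getattr(r, attr)]
    if not dists:
        return float("nan")
    return float(np.median(dists))


def results_frame(results: list[PromoterWindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "window_start": r.window[0],
                "window_end": r.window[1],
                "truncated": r.truncated,
                "sense_count": r.sense_count,
                "antisense_count": r.antisense_count,
                "bidirectional": r.bidirectional,
            }
            for r in results
        ]
    )
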