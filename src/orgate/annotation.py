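"""Genome-annotation model and tandem-array geometry.

Coordinates are 0-based half-open internally; GFF3/GTF files are 1-based
inclusive at the boundary. Odorant-receptor (OR) genes are not a standard
GFF biotype, so OR membership is assigned from user-supplied ID lists or a
gene-name regex; lncRNAs are recognised from ``gene_biotype`` attributes or
the same kind of rule.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    pass


def _check_intervals(ivs: list[Interval], name: str) -> None:
    for s, e in ivs:
        if e <= s:
            raise AnnotationError(f"empty or inverted {name} interval ({s}, {e})")
    if any(ivs[i][0] < ivs[i - 1][1] for i in range(1, len(ivs))):
        raise AnnotationError(f"{name} intervals overlap or are unsorted: {ivs}")


@dataclass
class GeneModel:
    """One strand-aware gene record with exon/CDS structure."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    biotype: str = "other"  # {'OR', 'lncRNA', 'other'}
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id}: empty span ({self.start}, {self.end})")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        _check_intervals(self.exons, "exon")
        _check_intervals(self.cds, "CDS")
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise AnnotationError(f"{self.gene_id}: exons outside gene span")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise AnnotationError(f"{self.gene_id}: CDS ({cs},{ce}) outside exons")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Annotated transcription start: 5'-most position on the gene's strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def overlaps(self, other: "GeneModel") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            L = self.chrom_lengths.get(g.chrom)
            if L is not None and g.end > L:
                raise AnnotationError(f"{g.gene_id}: span exceeds {g.chrom} length {L}")

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self.chrom_lengths.setdefault(gene.chrom, 0)
        self.chrom_lengths[gene.chrom] = max(self.chrom_lengths[gene.chrom], gene.end)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        """Genes on one chromosome in genomic order (start, then end)."""
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: (g.start, g.end, g.gene_id),
        )

    def by_biotype(self, biotype: str, include_pseudo: bool = True) -> list[GeneModel]:
        out = [
            g
            for g in self.genes.values()
            if g.biotype == biotype and (include_pseudo or not g.pseudogene)
        ]
        return sorted(out, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))

    @property
    def ors(self) -> list[GeneModel]:
        return self.by_biotype("OR")

    @property
    def lncrnas(self) -> list[GeneModel]:
        return self.by_biotype("lncRNA")


@dataclass
class TandemArray:
    """A chain of >=2 ORs with consecutive gaps below the chaining threshold.

    Inverted members are allowed; ``majority_strand`` is the modal strand of
    the member ORs and defines the array's transcription direction.
    """

    array_id: str
    chrom: str
    or_ids: list[str]
    majority_strand: str
    span: Interval

    def __len__(self) -> int:
        return len(self.or_ids)


@dataclass
class GenePair:
    """Two same-strand genes with a clean intergenic interval between them.

    ``upstream`` precedes ``downstream`` in the transcription direction of the
    shared strand; ``intergenic`` is the genomic interval between the two
    spans irrespective of strand.
    """

    upstream: GeneModel
    downstream: GeneModel
    intergenic: Interval
    pair_class: str  # {'OR', 'nonOR'}

    def __post_init__(self) -> None:
        if self.upstream.chrom != self.downstream.chrom:
            raise AnnotationError("pair members on different chromosomes")
        if self.upstream.strand != self.downstream.strand:
            raise AnnotationError("pair members on different strands")

    @property
    def pair_id(self) -> str:
        return f"{self.upstream.gene_id}|{self.downstream.gene_id}"

    @property
    def chrom(self) -> str:
        return self.upstream.chrom

    @property
    def strand(self) -> str:
        return self.upstream.strand

    @property
    def intergenic_length(self) -> int:
        return self.intergenic[1] - self.intergenic[0]


# ---------------------------------------------------------------------------
# Biotype rules and GFF/GTF input
# ---------------------------------------------------------------------------


def classify_biotype(
    gene_id: str,
    attributes: dict | None = None,
    *,
    or_ids: set[str] | frozenset[str] | None = None,
    or_regex: str | None = None,
    lnc_ids: set[str] | None = None,
    lnc_regex: str | None = None,
) -> str:
    """Assign {'OR','lncRNA','other'} to a gene from the configured rules."""
    if or_ids and gene_id in or_ids:
        return "OR"
    if or_regex and re.search(or_regex, gene_id):
        return "OR"
    if lnc_ids and gene_id in lnc_ids:
        return "lncRNA"
    if lnc_regex and re.search(lnc_regex, gene_id):
        return "lncRNA"
    if attributes:
        bt = attributes.get("gene_biotype") or attributes.get("biotype") or []
        if isinstance(bt, str):
            bt = [bt]
        if any(b in ("lncRNA", "lnc_RNA", "lincRNA") for b in bt):
            return "lncRNA"
    return "other"


def read_annotation(
    path: str,
    biotype_rules: dict | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    ``biotype_rules`` may contain ``or_ids``, ``or_regex``, ``lnc_ids``,
    ``lnc_regex`` and ``pseudogene_ids``. File coordinates (1-based
    inclusive) become 0-based half-open. Records with unknown strand are
    rejected with a warning; chromosome lengths default to the maximum
    annotated end per chromosome.
    """
    rules = dict(biotype_rules or {})
    pseudo_ids = set(rules.pop("pseudogene_ids", ()) or ())
    rules = {k: v for k, v in rules.items() if k in ("or_ids", "or_regex", "lnc_ids", "lnc_regex")}
    if rules.get("or_ids") is not None:
        rules["or_ids"] = set(rules["or_ids"])
    if rules.get("lnc_ids") is not None:
        rules["lnc_ids"] = set(rules["lnc_ids"])

    ann = GenomeAnnotation(chrom_lengths=dict(chrom_lengths or {}))
    if os.path.getsize(path) == 0 or not _has_records(path):
        return ann

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils reports the offending line
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    gene_types = [t for t in db.featuretypes() if t in ("gene", "pseudogene", "ncRNA_gene")]
    for ftype in gene_types:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            gid = feat.attributes.get("gene_id", [feat.id])[0] if feat.attributes else feat.id
            if feat.strand not in "+-":
                logger.warning("rejecting %s: unknown strand %r", gid, feat.strand)
                continue
            exons, cds = [], []
            for child in db.children(feat, featuretype=("exon", "CDS")):
                iv = (child.start - 1, child.end)
                (cds if child.featuretype == "CDS" else exons).append(iv)
            exons = _merge_intervals(exons)
            cds = _merge_intervals(cds)
            attrs = dict(feat.attributes) if feat.attributes else {}
            pseudo = (
                ftype == "pseudogene"
                or gid in pseudo_ids
                or attrs.get("pseudo", ["false"])[0].lower() in ("true", "1")
            )
            ann.add(
                GeneModel(
                    gene_id=gid,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=feat.start - 1,
                    end=feat.end,
                    exons=exons,
                    cds=cds,
                    biotype=classify_biotype(gid, attrs, **rules),
                    pseudogene=pseudo,
                )
            )
    if chrom_lengths:
        ann.chrom_lengths.update(chrom_lengths)
    return ann


def _has_records(path: str) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------


def detect_tandem_arrays(
    ann: GenomeAnnotation, max_gap: int = 10_000
) -> tuple[list[TandemArray], list[GeneModel]]:
    """Chain ORs into tandem arrays when consecutive gaps are <= ``max_gap``.

    Chaining is strand-agnostic (inverted members stay in the array). Returns
    ``(arrays, singletons)`` in deterministic chromosome/coordinate order. A
    strand tie is resolved to the first member's strand with a warning.
    """
    arrays: list[TandemArray] = []
    singletons: list[GeneModel] = []
    n = 0
    for chrom in sorted({g.chrom for g in ann.ors}):
        ors = [g for g in ann.genes_on(chrom) if g.biotype == "OR"]
        chain: list[GeneModel] = []
        for g in ors:
            if chain and g.start - max(x.end for x in chain) <= max_gap:
                chain.append(g)
            else:
                if chain:
                    arrays, singletons, n = _flush(chain, arrays, singletons, n)
                chain = [g]
        if chain:
            arrays, singletons, n = _flush(chain, arrays, singletons, n)
    return arrays, singletons


def _flush(chain, arrays, singletons, n):
    if len(chain) == 1:
        singletons.append(chain[0])
        return arrays, singletons, n
    counts = Counter(g.strand for g in chain)
    if len(counts) == 2 and counts["+"] == counts["-"]:
        strand = chain[0].strand
        logger.warning(
            "array of %s has a strand tie; using first member's strand %s",
            [g.gene_id for g in chain],
            strand,
        )
    else:
        strand = counts.most_common(1)[0][0]
    n += 1
    arrays.append(
        TandemArray(
            array_id=f"A{n}",
            chrom=chain[0].chrom,
            or_ids=[g.gene_id for g in chain],
            majority_strand=strand,
            span=(min(g.start for g in chain), max(g.end for g in chain)),
        )
    )
    return arrays, singletons, n


def flanking_genes(
    target: TandemArray | GeneModel, ann: GenomeAnnotation
) -> dict[str, GeneModel | None]:
    """Nearest non-OR gene on each side of an array (or singleton OR).

    Slots are ``upstream_same``, ``upstream_opposite``, ``downstream_same``
    and ``downstream_opposite``; upstream/downstream follow the target's
    transcription direction (majority strand for arrays) and same/opposite
    compare each candidate's strand to it. Genes overlapping the target span
    are skipped; an empty side leaves the slot ``None``.
    """
    if isinstance(target, TandemArray):
        chrom, span, ref_strand = target.chrom, target.span, target.majority_strand
        member = set(target.or_ids)
    else:
        chrom, span, ref_strand = target.chrom, target.span, target.strand
        member = {target.gene_id}
    left: dict[str, GeneModel] = {}
    right: dict[str, GeneModel] = {}
    for g in ann.genes_on(chrom):
        if g.biotype == "OR" or g.gene_id in member:
            continue
        rel = "same" if g.strand == ref_strand else "opposite"
        if g.end <= span[0]:
            if rel not in left or g.end > left[rel].end:
                left[rel] = g
        elif g.start >= span[1]:
            if rel not in right or g.start < right[rel].start:
                right[rel] = g
    up, down = (left, right) if ref_strand == "+" else (right, left)
    return {
        "upstream_same": up.get("same"),
        "upstream_opposite": up.get("opposite"),
        "downstream_same": down.get("same"),
        "downstream_opposite": down.get("opposite"),
    }


# ---------------------------------------------------------------------------
# Gene-pair sampling
# ---------------------------------------------------------------------------


def _pair_candidates(
    ann: GenomeAnnotation,
    cds_len_bounds: tuple[int, int],
    intergenic_bounds: tuple[int, int],
) -> list[GenePair]:
    """All gene pairs passing the four filters, in deterministic order.

    Filters: both genes have total CDS length within ``cds_len_bounds``; the
    members share a strand; the intergenic distance is within
    ``intergenic_bounds``; and neither gene nor the intergenic interval
    overlaps any other annotated gene on either strand.
    """
    lo_c, hi_c = cds_len_bounds
    lo_i, hi_i = intergenic_bounds
    out: list[GenePair] = []
    for chrom in sorted(ann.chrom_lengths):
        genes = ann.genes_on(chrom)
        for i, a in enumerate(genes):
            if not (lo_c <= a.cds_length <= hi_c):
                continue
            for b in genes[i + 1 :]:
                if b.start - a.end > hi_i:
                    break
                if b.strand != a.strand or not (lo_c <= b.cds_length <= hi_c):
                    continue
                gap = b.start - a.end
                if not (lo_i <= gap <= hi_i):
                    continue
                if any(
                    g.overlaps_interval(chrom, a.start, b.end)
                    for g in genes
                    if g.gene_id not in (a.gene_id, b.gene_id)
                ):
                    continue
                both_or = a.biotype == "OR" and b.biotype == "OR"
                neither_or = a.biotype != "OR" and b.biotype != "OR"
                if not (both_or or neither_or):
                    continue
                upstream, downstream = (a, b) if a.strand == "+" else (b, a)
                out.append(
                    GenePair(
                        upstream=upstream,
                        downstream=downstream,
                        intergenic=(a.end, b.start),
                        pair_class="OR" if both_or else "nonOR",
                    )
                )
    return out


def sample_gene_pairs(
    ann: GenomeAnnotation,
    cds_len_bounds: tuple[int, int] = (100, 10_000),
    intergenic_bounds: tuple[int, int] = (50, 10_000),
    n_nonor: int | None = None,
    seed: int = 0,
) -> tuple[list[GenePair], list[GenePair]]:
    """Exhaustive OR pairs plus a seeded uniform sample of non-OR pairs.

    ``n_nonor`` defaults to the number of OR pairs (an equal-size comparison
    group); if more are requested than exist, all are returned with a
    warning.
    """
    import numpy as np

    cands = _pair_candidates(ann, cds_len_bounds, intergenic_bounds)
    or_pairs = [p for p in cands if p.pair_class == "OR"]
    nonor = [p for p in cands if p.pair_class == "nonOR"]
    k = len(or_pairs) if n_nonor is None else n_nonor
    if k >= len(nonor):
        if k > len(nonor):
            logger.warning("requested %d non-OR pairs but only %d available", k, len(nonor))
        return or_pairs, nonor
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(nonor), size=k, replace=False))
    return or_pairs, [nonor[i] for i in idx]


# ---------------------------------------------------------------------------
# Antisense lncRNA geometry
# ---------------------------------------------------------------------------


def antisense_lncrna_overlap(ann: GenomeAnnotation) -> tuple[dict[str, bool], dict[str, float]]:
    """Which genes overlap an antisense lncRNA, and the per-class fractions.

    A gene overlaps an antisense lncRNA iff some lncRNA on the opposite
    strand shares at least one base with its span. Fractions are computed
    over non-pseudogene OR and non-OR (``other``) genes; lncRNAs themselves
    are not counted in either denominator.
    """
    lncs = ann.lncrnas
    flags: dict[str, bool] = {}
    counts = {"OR": [0, 0], "nonOR": [0, 0]}
    for g in ann.genes.values():
        if g.biotype == "lncRNA" or g.pseudogene:
            continue
        hit = any(l.strand != g.strand and l.overlaps(g) for l in lncs)
        flags[g.gene_id] = hit
        key = "OR" if g.biotype == "OR" else "nonOR"
        counts[key][0] += hit
        counts[key][1] += 1
    fracs = {
        f"frac_{k}": (c[0] / c[1] if c[1] else float("nan"))
        for k, c in (("OR", counts["OR"]), ("nonOR", counts["nonOR"]))
    }
    return flags, fracs


@dataclass
class NestedLnc:
    lncrna: GeneModel
    upstream_or: GeneModel | None
    downstream_or: GeneModel | None
    dist_upstream: int | None  # TSS-to-TSS, bp
    dist_downstream: int | None


def nested_lncrnas(array: TandemArray, ann: GenomeAnnotation) -> list[NestedLnc]:
    """lncRNAs overlapping an array span, with nearest ORs by TSS.

    Up/downstream are taken in the array's transcription direction relative
    to the lncRNA's own TSS; distances are non-negative TSS-to-TSS.
    """
    sgn = 1 if array.majority_strand == "+" else -1
    or_tss = sorted(
        ((ann[oid].tss, oid) for oid in array.or_ids), key=lambda t: sgn * t[0]
    )  # transcription order
    out = []
    for lnc in ann.lncrnas:
        if lnc.chrom != array.chrom or not lnc.overlaps_interval(array.chrom, *array.span):
            continue
        up = down = None
        for tss, oid in or_tss:
            if sgn * tss <= sgn * lnc.tss:
                up = oid
            elif down is None:
                down = oid
        out.append(
            NestedLnc(
                lncrna=lnc,
                upstream_or=ann[up] if up else None,
                downstream_or=ann[down] if down else None,
                dist_upstream=abs(lnc.tss - ann[up].tss) if up else None,
                dist_downstream=abs(lnc.tss - ann[down].tss) if down else None,
            )
        )
    return out


def anchor_tss(gene: GeneModel, mode: str = "annotated") -> int:
    """Strand-aware 5' anchor: the annotated TSS or the first-CDS start.

    OR gene models often carry unreliable UTRs, so promoter windows for ORs
    are anchored at the first CDS instead of the annotated TSS.
    """
    if mode == "annotated":
        return gene.tss
    if mode == "first_cds":
        if not gene.cds:
            raise AnnotationError(f"{gene.gene_id}: first_cds anchor requires a CDS")
        return gene.cds[0][0] if gene.strand == "+" else gene.cds[-1][1]
    raise ValueError(f"unknown anchor mode {mode!r}")


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------


def write_arrays_bed(arrays: list[TandemArray], path: str) -> None:
    """Write arrays as BED6 (name = array id, score = member count)."""
    with open(path, "w") as fh:
        for a in arrays:
            fh.write(
                f"{a.chrom}\t{a.span[0]}\t{a.span[1]}\t{a.array_id}\t{len(a)}\t{a.majority_strand}\n"
            )


def write_pairs_tsv(pairs: list[GenePair], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "pair_id": p.pair_id,
            "chrom": p.chrom,
            "strand": p.strand,
            "upstream": p.upstream.gene_id,
            "downstream": p.downstream.gene_id,
            "intergenic_start": p.intergenic[0],
            "intergenic_end": p.intergenic[1],
            "pair_class": p.pair_class,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
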