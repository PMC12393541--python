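"""Seeded generators emulating the data structures the analyses assume.

Each generator returns both the dataset and its ground truth so recovery can
be tested end to end without any external data: tandem arrays of head-to-tail
ORs with optional inversions and nested antisense lncRNAs; stranded coverage
with downstream readthrough decay and promoter-proximal antisense signal;
twin sense/antisense start-site peaks with the antisense peak farther
upstream; negative-binomial count matrices with the staircase coexpression
structure and lncRNA/upstream-OR anti-correlation; and confocal stacks with
depth-attenuated DAPI and nuclear/cytoplasmic FISH signal.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import ndimage

from orgate.annotation import GeneModel, GenomeAnnotation, GenePair, TandemArray
from orgate.coverage import StrandedCoverageTrack
from orgate.fishquant import ImageStack
from orgate.tss import TssTrack

MARKER_GENES = [f"marker{i}" for i in range(1, 6)]


@dataclass
class LncTruth:
    lnc_id: str
    partner_or: str  # chosen OR sharing the bidirectional promoter
    upstream_or: str | None  # OR suppressed by the lncRNA
    downstream_or: str | None
    distance: float  # partner-OR TSS to lncRNA 3' end, bp


@dataclass
class AnnotationTruth:
    seed: int
    array_strands: dict[str, str] = field(default_factory=dict)
    inverted_ors: list[str] = field(default_factory=list)
    lncs: list[LncTruth] = field(default_factory=list)
    or_pair_ids: list[str] = field(default_factory=list)
    nonor_pair_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _make_or(gene_id, chrom, strand, start, gene_len) -> GeneModel:
    # two exons, fully coding; CDS length = 0.8 * gene_len
    e1 = (start, start + int(gene_len * 0.4))
    e2 = (start + int(gene_len * 0.6), start + gene_len)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=start + gene_len,
        exons=[e1, e2], cds=[e1, e2], biotype="OR",
    )


def gen_annotation(
    seed: int = 0,
    n_arrays: int = 4,
    array_size_range: tuple[int, int] = (3, 6),
    gene_len: int = 2000,
    gap_range: tuple[int, int] = (1000, 6000),
    inversion_rate: float = 0.0,
    lnc_per_array: int = 1,
    lnc_len: int = 1500,
    lnc_promoter_gap: int = 300,
    flank_genes: bool = True,
    n_nonor_pairs: int = 8,
    locus_spacing: int = 30_000,
    chrom: str = "chr1",
) -> tuple[GenomeAnnotation, list[TandemArray], AnnotationTruth]:
    """Synthetic genome: OR tandem arrays, nested lncRNAs, flanks, non-OR pairs.

    Arrays are head-to-tail chains of two-exon ORs separated by gaps drawn
    from ``gap_range``; members are independently inverted with probability
    ``inversion_rate``. Each array hosts ``lnc_per_array`` antisense lncRNAs
    placed upstream-adjacent to a designated partner OR (never the first in
    transcription order), so the lncRNA 3' end sits
    ``lnc_promoter_gap + lnc_len`` bp from the partner TSS and the body
    overlaps the upstream OR. Flanking non-OR genes sit on both strands on
    both sides of each array, and isolated same-strand non-OR pairs satisfy
    the standard gene-pair filters.
    """
    if gap_range[0] < 1 or array_size_range[0] < 2:
        raise ValueError("infeasible generator parameters")
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    truth = AnnotationTruth(seed=seed)
    arrays: list[TandemArray] = []
    x = 20_000

    for a in range(n_arrays):
        size = int(rng.integers(array_size_range[0], array_size_range[1] + 1))
        strand = "+"  # array direction; inversions flip individual members
        start_x = x
        ors: list[GeneModel] = []
        for i in range(size):
            if i > 0:
                x += int(rng.integers(gap_range[0], gap_range[1] + 1))
            s = strand if rng.random() >= inversion_rate else "-"
            g = _make_or(f"ORA{a}G{i}", chrom, s, x, gene_len)
            if s != strand:
                truth.inverted_ors.append(g.gene_id)
            ann.add(g)
            ors.append(g)
            x = g.end
        array = TandemArray(
            array_id=f"T{a + 1}",
            chrom=chrom,
            or_ids=[g.gene_id for g in ors],
            majority_strand=strand,
            span=(ors[0].start, ors[-1].end),
        )
        arrays.append(array)
        truth.array_strands[array.array_id] = strand

        # nested antisense lncRNAs, partnered with an interior OR (so both
        # flanking roles exist); fall back to the last OR in 2-gene arrays
        candidates = [i for i in range(1, size - 1) if ors[i].strand == strand] or [
            i for i in range(1, size) if ors[i].strand == strand
        ]
        rng.shuffle(candidates)
        for j in range(min(lnc_per_array, len(candidates))):
            i = candidates[j]
            partner = ors[i]
            lnc_end = partner.start - lnc_promoter_gap
            lnc_start = lnc_end - lnc_len
            lnc = GeneModel(
                gene_id=f"LNC{a}N{j}", chrom=chrom, strand="-",
                start=lnc_start, end=lnc_end, biotype="lncRNA",
            )
            ann.add(lnc)
            truth.lncs.append(
                LncTruth(
                    lnc_id=lnc.gene_id,
                    partner_or=partner.gene_id,
                    upstream_or=ors[i - 1].gene_id if i > 0 else None,
                    downstream_or=ors[i + 1].gene_id if i + 1 < size else None,
                    distance=float(partner.tss - lnc.start),
                )
            )

        if flank_genes:
            for side, pos in (("L", start_x - 10_000), ("R", x + 8_000)):
                for st, off in (("+", 0), ("-", 3000)):
                    g = GeneModel(
                        gene_id=f"FLK{a}{side}{'m' if st == '-' else 'p'}",
                        chrom=chrom, strand=st,
                        start=pos + off, end=pos + off + 1500,
                        cds=[(pos + off, pos + off + 1500)], biotype="other",
                    )
                    ann.add(g)
        x += locus_spacing

    # isolated non-OR pairs passing the gene-pair filters
    for p in range(n_nonor_pairs):
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(800, 3000))
        gap = int(rng.integers(200, 8000))
        g1 = GeneModel(
            gene_id=f"NP{p}A", chrom=chrom, strand=strand, start=x, end=x + glen,
            cds=[(x, x + glen)], biotype="other",
        )
        x2 = x + glen + gap
        g2 = GeneModel(
            gene_id=f"NP{p}B", chrom=chrom, strand=strand, start=x2, end=x2 + glen,
            cds=[(x2, x2 + glen)], biotype="other",
        )
        ann.add(g1)
        ann.add(g2)
        up, down = (g1, g2) if strand == "+" else (g2, g1)
        truth.nonor_pair_ids.append(f"{up.gene_id}|{down.gene_id}")
        x = x2 + glen + locus_spacing

    ann.chrom_lengths[chrom] = x + 20_000
    # consecutive OR pairs not disrupted by inversions or a nested lncRNA
    for a in arrays:
        for i in range(len(a) - 1):
            g1, g2 = ann[a.or_ids[i]], ann[a.or_ids[i + 1]]
            clean = g1.strand == g2.strand and not any(
                o.overlaps_interval(chrom, g1.start, g2.end)
                for o in ann.genes.values()
                if o.gene_id not in (g1.gene_id, g2.gene_id)
            )
            if clean:
                truth.or_pair_ids.append(f"{g1.gene_id}|{g2.gene_id}")
    return ann, arrays, truth


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in sorted(ann.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            bt = ";gene_biotype=lncRNA" if g.biotype == "lncRNA" else ""
            ps = ";pseudo=true" if g.pseudogene else ""
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}{bt}{ps}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{k};Parent={g.gene_id}\n"
                )
            for k, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.c{k};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def gen_coverage(
    ann: GenomeAnnotation,
    pairs: list[GenePair],
    promoter_rate: float = 50.0,
    readthrough_decay_per_kb: float = 0.2,
    nonor_decay_per_kb: float = 3.0,
    antisense_fraction: float = 0.5,
    nonor_antisense_fraction: float = 0.005,
    poisson_noise: bool = True,
    seed: int = 0,
) -> StrandedCoverageTrack:
    """Stranded coverage with readthrough decay and antisense signal per pair.

    For each pair, sense depth is ``promoter_rate`` over the upstream gene
    and decays exponentially with downstream distance; each downstream
    region (intergenic span, downstream gene) is deposited uniformly at the
    rate evaluated at its midpoint, which keeps the expected relative
    coverage in closed form. Antisense depth mirrors the sense profile
    scaled by the class's antisense fraction. Per-base depths are Poisson
    sampled unless ``poisson_noise`` is off.
    """
    rng = np.random.default_rng(seed)
    lam = StrandedCoverageTrack(ann.chrom_lengths)
    for pair in pairs:
        decay = readthrough_decay_per_kb if pair.pair_class == "OR" else nonor_decay_per_kb
        af = antisense_fraction if pair.pair_class == "OR" else nonor_antisense_fraction
        sense, anti = pair.strand, "-" if pair.strand == "+" else "+"
        up, down = pair.upstream, pair.downstream
        ig_len = pair.intergenic_length
        regions = [(up.start, up.end, 0.0)]
        if ig_len > 0:
            regions.append((*pair.intergenic, ig_len / 2.0))
        regions.append((down.start, down.end, ig_len + down.length / 2.0))
        for start, end, dist in regions:
            rate = promoter_rate * math.exp(-decay * dist / 1000.0)
            lam.add_interval(pair.chrom, sense, start, end, rate)
            if af > 0:
                lam.add_interval(pair.chrom, anti, start, end, af * rate)
    if not poisson_noise:
        return lam
    out = StrandedCoverageTrack(ann.chrom_lengths)
    for chrom in lam.depth:
        for s in "+-":
            arr = lam.depth[chrom][s]
            nz = np.flatnonzero(arr)
            if len(nz):
                out.depth[chrom][s][nz] = rng.poisson(arr[nz]).astype(float)
    return out


def expected_intergenic_relcov(pair: GenePair, decay_per_kb: float) -> float:
    """Closed-form expected intergenic relative coverage for one pair."""
    return math.exp(-decay_per_kb * pair.intergenic_length / 2.0 / 1000.0)


# ---------------------------------------------------------------------------
# Start sites
# ---------------------------------------------------------------------------


def gen_tss(
    ann: GenomeAnnotation,
    genes: list[GeneModel],
    anchors: dict[str, int],
    sense_offset: tuple[float, float] = (200.0, 60.0),
    antisense_offset: tuple[float, float] = (500.0, 60.0),
    reads_per_gene: int = 50,
    bidir_fraction: float = 0.34,
    window_bp: int = 1000,
    poisson_counts: bool = True,
    seed: int = 0,
) -> tuple[TssTrack, dict[str, bool]]:
    """Twin-peak start-site track: sense peak plus, for an exact
    ``round(bidir_fraction * n)``-gene subset, an antisense peak farther
    upstream.

    Offsets are Normal(mean, sd) per read, clipped into the promoter window;
    read counts are Poisson(``reads_per_gene``) unless ``poisson_counts`` is
    off, in which case exactly ``reads_per_gene`` reads are placed per peak.
    Returns the track and the per-gene bidirectionality truth.
    """
    rng = np.random.default_rng(seed)
    track = TssTrack(ann.chrom_lengths)
    n_bidir = int(round(bidir_fraction * len(genes)))
    bidir_idx = set(rng.choice(len(genes), size=n_bidir, replace=False)) if n_bidir else set()
    truth: dict[str, bool] = {}
    for i, gene in enumerate(genes):
        anchor = anchors[gene.gene_id]
        anti = "-" if gene.strand == "+" else "+"
        bidir = i in bidir_idx
        truth[gene.gene_id] = bidir
        peaks = [(gene.strand, sense_offset)]
        if bidir:
            peaks.append((anti, antisense_offset))
        for strand, (mu, sd) in peaks:
            n = int(rng.poisson(reads_per_gene)) if poisson_counts else reads_per_gene
            if n == 0:
                continue
            offs = np.clip(np.round(rng.normal(mu, sd, size=n)), 0, window_bp - 1).astype(int)
            for off in offs:
                pos = anchor - off if gene.strand == "+" else anchor + off
                if 0 <= pos < ann.chrom_lengths[gene.chrom]:
                    track.add(gene.chrom, strand, int(pos), 1)
    # a gene with zero placed sense reads cannot be recovered; only possible
    # under Poisson counts, where truth reflects placement, not intent
    return track, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with mean ``mean`` and shape ``dispersion``."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def gen_counts(
    ann: GenomeAnnotation,
    arrays: list[TandemArray],
    truth: AnnotationTruth,
    n_cells: int = 1000,
    chosen_mean: float = 100.0,
    downstream_decay: float = 1.5,
    lnc_mean: float = 30.0,
    leak_mean: float = 5.0,
    lnc_coupling: float = 0.12,
    background_rate: float = 0.05,
    n_housekeeping: int = 60,
    housekeeping_mean: float = 120.0,
    marker_base: int = 2,
    marker_extra: float = 3.0,
    nb_dispersion: float = 20.0,
    promoter_strength_shape: float = 10.0,
    partner_bias: float | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """UMI count matrix with staircase coexpression and lncRNA coupling.

    Each cell picks an array uniformly and a promoter OR uniformly within it
    (in transcription order). With per-cell promoter strength
    ``s ~ Gamma(shape, 1/shape)``: the chosen OR draws
    ``NB(chosen_mean * s)``; downstream ORs at rank r draw
    ``NB(chosen_mean * s * exp(-downstream_decay * r))``; a partnered
    antisense lncRNA draws ``NB(lnc_mean * s)`` and suppresses leakage of
    the OR immediately upstream, ``NB(leak_mean * exp(-lnc_coupling *
    lnc_count))`` (independent of ``s``, so coupling 0 decorrelates it).
    Marker genes are ``marker_base + Poisson(marker_extra)`` so the neuron
    filter keeps every cell; ``n_housekeeping`` housekeeping genes at
    ``Poisson(housekeeping_mean)`` give every cell a stable transcriptome
    background (without it, per-cell normalization is dominated by the
    chosen OR and becomes compositional); all other genes are sparse
    Poisson background.

    ``partner_bias`` is the probability that a cell's promoter is its
    array's lncRNA-partner OR rather than a uniform draw. It emulates a
    correlation-study sample conditioned on cells whose chosen OR has a
    nearby upstream lncRNA, which concentrates cells into the qualifying
    groups.

    Returns the AnnData of counts and a per-cell truth table.
    """
    rng = np.random.default_rng(seed)
    hk_genes = [f"hk{i}" for i in range(n_housekeeping)]
    var_names = list(ann.genes) + MARKER_GENES + hk_genes
    gi = {g: i for i, g in enumerate(var_names)}
    X = np.zeros((n_cells, len(var_names)), dtype=np.int64)

    lnc_by_partner = {t.partner_or: t for t in truth.lncs}
    order_of = {}
    for a in arrays:
        order = sorted(a.or_ids, key=lambda g: ann[g].start)
        if a.majority_strand == "-":
            order = order[::-1]
        order_of[a.array_id] = order

    rows = []
    arr_idx = rng.integers(0, len(arrays), size=n_cells)
    strengths = rng.gamma(promoter_strength_shape, 1.0 / promoter_strength_shape, size=n_cells)
    for c in range(n_cells):
        a = arrays[arr_idx[c]]
        order = order_of[a.array_id]
        partner = next((t.partner_or for t in truth.lncs if t.partner_or in order), None)
        if partner is not None and partner_bias and rng.random() < partner_bias:
            k = order.index(partner)
        else:
            k = int(rng.integers(0, len(order)))
        chosen = order[k]
        s = strengths[c]
        X[c, gi[chosen]] = _nb(rng, chosen_mean * s, nb_dispersion)
        for r, oid in enumerate(order[k + 1 :], start=1):
            if math.isfinite(downstream_decay):
                X[c, gi[oid]] = _nb(rng, chosen_mean * s * math.exp(-downstream_decay * r), nb_dispersion)
        lnc_val = 0
        t = lnc_by_partner.get(chosen)
        if t is not None:
            lnc_val = int(_nb(rng, lnc_mean * s, nb_dispersion))
            X[c, gi[t.lnc_id]] = lnc_val
        if k > 0:
            upstream = order[k - 1]
            X[c, gi[upstream]] += _nb(
                rng, leak_mean * math.exp(-lnc_coupling * lnc_val), nb_dispersion
            )
        rows.append(
            {"cell_id": f"cell{c}", "true_array_id": a.array_id, "chosen_promoter": chosen,
             "lnc_id": t.lnc_id if t else None, "strength": s}
        )

    for m in MARKER_GENES:
        X[:, gi[m]] = marker_base + rng.poisson(marker_extra, size=n_cells)
    for h in hk_genes:
        X[:, gi[h]] = rng.poisson(housekeeping_mean, size=n_cells)
    bg = rng.poisson(background_rate, size=X.shape)
    bg[:, [gi[g] for g in MARKER_GENES + hk_genes]] = 0
    X += bg

    adata = ad.AnnData(
        X=X.astype(np.float64),
        obs=pd.DataFrame(index=[f"cell{c}" for c in range(n_cells)]),
        var=pd.DataFrame(index=var_names),
    )
    return adata, pd.DataFrame(rows).set_index("cell_id")


def write_mtx(adata: ad.AnnData, prefix: str) -> None:
    """Write counts as MTX triplet plus genes/barcodes TSVs."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(f"{prefix}matrix.mtx", sparse.coo_matrix(adata.X))
    pd.Series(adata.var_names).to_csv(f"{prefix}genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(f"{prefix}barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx(prefix: str) -> ad.AnnData:
    from scipy import io as sio

    X = np.asarray(sio.mmread(f"{prefix}matrix.mtx").todense())
    genes = pd.read_csv(f"{prefix}genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(f"{prefix}barcodes.tsv", sep="\t", header=None)[0].tolist()
    return ad.AnnData(
        X=X.astype(np.float64),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

CELL_CLASSES = ("chosen", "nuclear-only", "negative")


@dataclass
class CellTruth:
    cell_id: int
    z: int
    center: tuple[int, int]
    radius: int
    cell_class: str


def gen_stack(
    seed: int = 0,
    shape: tuple[int, int, int, int] = (6, 2, 256, 256),
    n_cells: int = 12,
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    nucleus_radius_range: tuple[int, int] = (12, 16),
    dapi_attenuation: float = 0.9,
    dapi_base: float = 150.0,
    dapi_background: float = 40.0,
    nuclear_intensity: float = 200.0,
    nuclear_only_intensity: float = 80.0,
    ring_intensity: float = 160.0,
    ring_px: int = 3,
    psf_sigma: float = 1.0,
    background: float = 3.0,
    noise: float = 0.0,
) -> tuple[ImageStack, np.ndarray, list[CellTruth]]:
    """Confocal z-stack with ground-truth nuclei and per-cell classes.

    Channel 0 is DAPI, channel 1 the FISH probe. Cells are disks assigned
    round-robin to slices and classes ('chosen' fills nucleus and the
    ``ring_px`` cytoplasmic annulus; 'nuclear-only' fills the nucleus at a
    lower level; 'negative' has no probe signal). Every slice is attenuated
    by ``dapi_attenuation**z`` across all channels, then blurred with a
    Gaussian PSF, Poisson-sampled, and Gaussian noise of sd ``noise`` added.
    Nuclear radii are drawn so areas fall inside the 400-900 px gate.
    Returns the stack, per-slice ground-truth label masks, and cell truths.
    """
    nz, nc, ny, nx = shape
    if nc < 2:
        raise ValueError("need at least DAPI + one signal channel")
    rng = np.random.default_rng(seed)
    n_classes = [int(round(f * n_cells)) for f in class_mix]
    while sum(n_classes) < n_cells:
        n_classes[0] += 1
    while sum(n_classes) > n_cells:
        n_classes[int(np.argmax(n_classes))] -= 1
    classes = [c for c, n in zip(CELL_CLASSES, n_classes) for _ in range(n)]
    rng.shuffle(classes)

    signal = np.zeros(shape, dtype=float)
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    truths: list[CellTruth] = []
    margin = nucleus_radius_range[1] + ring_px + 4
    min_sep = 2 * (nucleus_radius_range[1] + ring_px) + 5
    centers_by_slice: dict[int, list[tuple[int, int]]] = {z: [] for z in range(nz)}
    yy, xx = np.mgrid[0:ny, 0:nx]

    for cid, cls in enumerate(classes, start=1):
        z = (cid - 1) % nz
        r = int(rng.integers(nucleus_radius_range[0], nucleus_radius_range[1] + 1))
        for _ in range(200):
            cy = int(rng.integers(margin, ny - margin))
            cx = int(rng.integers(margin, nx - margin))
            if all(
                (cy - y0) ** 2 + (cx - x0) ** 2 >= min_sep**2
                for y0, x0 in centers_by_slice[z]
            ):
                break
        else:
            raise RuntimeError("could not place all nuclei; reduce n_cells or enlarge the field")
        centers_by_slice[z].append((cy, cx))
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = dist2 <= r**2
        ring = (dist2 <= (r + ring_px) ** 2) & ~nucleus
        labels[z][nucleus] = cid
        level = float(rng.normal(1.0, 0.05))
        if cls == "chosen":
            signal[z, 1][nucleus] += nuclear_intensity * level
            signal[z, 1][ring] += ring_intensity * level
        elif cls == "nuclear-only":
            signal[z, 1][nucleus] += nuclear_only_intensity * level
        signal[z, 0][nucleus] += dapi_base
        truths.append(CellTruth(cid, z, (cy, cx), r, cls))

    signal[:, 0] += dapi_background
    signal[:, 1] += background
    data = np.empty(shape, dtype=float)
    for z in range(nz):
        att = dapi_attenuation**z
        for ch in range(nc):
            blurred = ndimage.gaussian_filter(signal[z, ch] * att, sigma=psf_sigma)
            data[z, ch] = rng.poisson(np.clip(blurred, 0, None))
    if noise > 0:
        data = np.clip(data + rng.normal(0, noise, size=shape), 0, None)
    return ImageStack(data, dapi_channel=0), labels, truths
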