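import numpy as np
import pytest

from orgate import annotation as A
from tests.conftest import make_annotation, make_gene, random_toy_annotation
from tests.oracles import brute_flanking, brute_pair_filter, chain_components


# ---------------------------------------------------------------------------
# GFF/GTF input
# ---------------------------------------------------------------------------


GFF_TOY = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA
chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tID=geneB
chr1\tsrc\tgene\t5001\t6000\t.\t+\t.\tID=geneC
chr1\tsrc\texon\t5001\t5400\t.\t+\t.\tID=geneC.e0;Parent=geneC
chr1\tsrc\tCDS\t5001\t5400\t.\t+\t0\tID=geneC.c0;Parent=geneC
"""


def test_read_annotation_biotype_rules_and_coordinates(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF_TOY)
    ann = A.read_annotation(str(path), {"or_ids": ["geneA"]})
    assert [ann[g].biotype for g in ("geneA", "geneB", "geneC")] == ["OR", "other", "other"]
    # 1-based inclusive on disk -> 0-based half-open in memory
    assert ann["geneA"].span == (100, 200)
    assert ann["geneC"].cds == [(5000, 5400)]


def test_read_annotation_empty_file(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("")
    assert len(A.read_annotation(str(path))) == 0


def test_read_annotation_unknown_strand_rejected(tmp_path):
    path = tmp_path / "strand.gff3"
    path.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t100\t.\t.\t.\tID=gX\n")
    ann = A.read_annotation(str(path))
    assert "gX" not in ann.genes


def test_gene_model_invariants():
    with pytest.raises(A.AnnotationError):
        make_gene("bad", 100, 100)  # empty span
    with pytest.raises(A.AnnotationError):
        A.GeneModel("bad", "chr1", "+", 0, 100, exons=[(0, 50)], cds=[(60, 80)])


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------


def _ors(gaps, strands=None, gene_len=1000):
    genes, x = [], 0
    for i, gap in enumerate([0] + list(gaps)):
        x += gap
        genes.append(
            make_gene(f"or{i}", x, x + gene_len, strand=(strands or "+" * 10)[i], biotype="OR")
        )
        x += gene_len
    return genes


@pytest.mark.parametrize(
    "gaps,expected_sizes,expected_singletons",
    [
        ((5000, 8000), [3], 0),
        ((5000, 12000), [2], 1),
        ((12000, 12000), [], 3),
    ],
)
def test_array_chaining_gap_rule(gaps, expected_sizes, expected_singletons):
    ann = make_annotation(_ors(gaps))
    arrays, singles = A.detect_tandem_arrays(ann, max_gap=10_000)
    assert [len(a) for a in arrays] == expected_sizes
    assert len(singles) == expected_singletons


def test_array_majority_strand_with_inversion():
    ann = make_annotation(_ors((5000,) * 4, strands="++-++"))
    arrays, singles = A.detect_tandem_arrays(ann)
    assert len(arrays) == 1 and not singles
    assert arrays[0].majority_strand == "+"
    assert arrays[0].or_ids == [f"or{i}" for i in range(5)]


def test_array_chaining_matches_transitive_closure_oracle(rng):
    for _ in range(50):
        ann = random_toy_annotation(rng, n_genes=int(rng.integers(2, 20)), or_prob=0.8)
        arrays, singles = A.detect_tandem_arrays(ann, max_gap=10_000)
        got = sorted(
            [a.or_ids for a in arrays] + [[s.gene_id] for s in singles]
        )
        want = sorted([[g.gene_id for g in c] for c in chain_components(ann.ors, 10_000)])
        assert got == want


# ---------------------------------------------------------------------------
# Flanking genes
# ---------------------------------------------------------------------------


def test_flanking_plus_strand_array():
    ors = _ors((5000,))
    after = ors[-1].end
    down_same = make_gene("ds", after + 2000, after + 3000, strand="+")
    down_opp = make_gene("do", after + 4000, after + 5000, strand="-")
    ann = make_annotation(ors + [down_same, down_opp])
    arrays, _ = A.detect_tandem_arrays(ann)
    slots = A.flanking_genes(arrays[0], ann)
    assert slots["downstream_same"].gene_id == "ds"
    assert slots["downstream_opposite"].gene_id == "do"
    assert slots["upstream_same"] is None


def test_flanking_minus_strand_array_reverses_sides():
    low = make_gene("low", 0, 500, strand="-")
    genes = []
    x = 2000
    for i in range(2):
        genes.append(make_gene(f"or{i}", x, x + 1000, strand="-", biotype="OR"))
        x += 6000
    ann = make_annotation([low] + genes)
    arrays, _ = A.detect_tandem_arrays(ann)
    slots = A.flanking_genes(arrays[0], ann)
    # minus-strand array: lower coordinates are downstream
    assert slots["downstream_same"].gene_id == "low"
    assert slots["upstream_same"] is None


def test_flanking_matches_exhaustive_oracle(rng):
    for _ in range(25):
        ann = random_toy_annotation(rng, n_genes=15, or_prob=0.5)
        arrays, singles = A.detect_tandem_arrays(ann)
        for target in arrays + singles:
            got = A.flanking_genes(target, ann)
            if isinstance(target, A.TandemArray):
                span, strand, members = target.span, target.majority_strand, set(target.or_ids)
            else:
                span, strand, members = target.span, target.strand, {target.gene_id}
            want = brute_flanking(span, strand, members, ann.genes.values())
            assert {k: v and v.gene_id for k, v in got.items()} == {
                k: v and v.gene_id for k, v in want.items()
            }


# ---------------------------------------------------------------------------
# Gene pairs
# ---------------------------------------------------------------------------


def _isolated_pair(gap=2000, cds_len=500, strand="+", cls="other", x0=0):
    a = make_gene("pa", x0, x0 + 1000, strand=strand, biotype=cls, cds=[(x0, x0 + cds_len)])
    b0 = x0 + 1000 + gap
    b = make_gene("pb", b0, b0 + 1000, strand=strand, biotype=cls, cds=[(b0, b0 + cds_len)])
    return [a, b]


def test_pair_filters_basic():
    ann = make_annotation(_isolated_pair())
    _, nonor = A.sample_gene_pairs(ann, n_nonor=5)
    assert [p.pair_id for p in nonor] == ["pa|pb"]

    ann = make_annotation(_isolated_pair(gap=12_000))
    _, nonor = A.sample_gene_pairs(ann, n_nonor=5)
    assert nonor == []

    # antisense gene overlapping the intergenic interval excludes the pair
    genes = _isolated_pair()
    genes.append(make_gene("anti", 1500, 1800, strand="-"))
    _, nonor = A.sample_gene_pairs(make_annotation(genes), n_nonor=5)
    assert nonor == []


def test_pair_sampling_deterministic_and_order_invariant(rng):
    ann = random_toy_annotation(rng, n_genes=18, or_prob=0.3)
    or1, non1 = A.sample_gene_pairs(ann, n_nonor=2, seed=42)
    # rebuild with gene records inserted in reverse order
    ann2 = make_annotation(list(ann.genes.values())[::-1], ann.chrom_lengths)
    or2, non2 = A.sample_gene_pairs(ann2, n_nonor=2, seed=42)
    assert [p.pair_id for p in or1] == [p.pair_id for p in or2]
    assert [p.pair_id for p in non1] == [p.pair_id for p in non2]


def test_pairs_match_brute_force_oracle(rng):
    for _ in range(25):
        ann = random_toy_annotation(rng, n_genes=int(rng.integers(4, 16)))
        or_pairs, nonor = A.sample_gene_pairs(ann, n_nonor=10**6, seed=0)
        want = brute_pair_filter(ann)
        assert {p.pair_id for p in or_pairs} == want["OR"]
        assert {p.pair_id for p in nonor} == want["nonOR"]


# ---------------------------------------------------------------------------
# Antisense lncRNA overlap & nesting
# ---------------------------------------------------------------------------


def test_antisense_overlap_counting():
    genes = []
    for i in range(4):
        genes.append(make_gene(f"or{i}", i * 10_000, i * 10_000 + 1000, biotype="OR"))
    for i in range(10):
        genes.append(make_gene(f"n{i}", 100_000 + i * 10_000, 100_000 + i * 10_000 + 1000))
    genes.append(make_gene("lnc", 200, 600, strand="-", biotype="lncRNA"))  # inside or0
    genes.append(make_gene("lnc_same", 10_200, 10_600, strand="+", biotype="lncRNA"))
    flags, fracs = A.antisense_lncrna_overlap(make_annotation(genes))
    assert flags["or0"] and not flags["or1"]  # same-strand lncRNA does not count
    assert fracs == {"frac_OR": 0.25, "frac_nonOR": 0.0}


def test_nested_lncrna_neighbors_and_distances():
    ors = _ors((5000, 5000, 5000))
    # lncRNA TSS (its high coordinate, '-' strand) between or1 and or2
    lnc = make_gene("lnc", ors[1].end + 500, ors[2].start - 500, strand="-", biotype="lncRNA")
    ann = make_annotation(ors + [lnc])
    arrays, _ = A.detect_tandem_arrays(ann)
    nested = A.nested_lncrnas(arrays[0], ann)
    assert len(nested) == 1
    rec = nested[0]
    assert rec.upstream_or.gene_id == "or1" and rec.downstream_or.gene_id == "or2"
    assert rec.dist_upstream == abs(lnc.tss - ors[1].tss)
    assert rec.dist_downstream == abs(ors[2].tss - lnc.tss)
    # a lncRNA outside the array span is not returned
    far = make_gene("far", 10**6, 10**6 + 500, strand="-", biotype="lncRNA")
    ann2 = make_annotation(ors + [far])
    arrays2, _ = A.detect_tandem_arrays(ann2)
    assert A.nested_lncrnas(arrays2[0], ann2) == []


# ---------------------------------------------------------------------------
# TSS anchors
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "strand,expected", [("+", 1000), ("-", 1500)]
)
def test_anchor_first_cds_is_strand_aware(strand, expected):
    g = make_gene("g", 900, 1600, strand=strand, exons=[(900, 1600)], cds=[(1000, 1500)])
    assert A.anchor_tss(g, "first_cds") == expected


def test_anchor_modes_and_errors():
    g = make_gene("g", 900, 1600, strand="+")
    assert A.anchor_tss(g, "annotated") == 900
    with pytest.raises(A.AnnotationError):
        A.anchor_tss(g, "first_cds")  # CDS-less gene (e.g. lncRNA)
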