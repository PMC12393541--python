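"""Independent brute-force oracles used by the tests.

These deliberately re-derive each quantity from first principles (exhaustive
enumeration, per-base sums, closed forms) without calling the library code
paths they check.
"""

from itertools import combinations

import numpy as np


def interval_distance(a, b):
    """Gap between two genes' spans (0 when overlapping)."""
    return max(b.start - a.end, a.start - b.end, 0)


def chain_components(ors, max_gap):
    """Single-linkage components of ORs under span distance <= max_gap.

    Transitive closure via union-find over all OR pairs.
    """
    ors = sorted(ors, key=lambda g: (g.chrom, g.start, g.gene_id))
    parent = list(range(len(ors)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(ors)), 2):
        if ors[i].chrom == ors[j].chrom and interval_distance(ors[i], ors[j]) <= max_gap:
            parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i, g in enumerate(ors):
        comps.setdefault(find(i), []).append(g)
    out = [sorted(c, key=lambda g: g.start) for c in comps.values()]
    return sorted(out, key=lambda c: (c[0].chrom, c[0].start))


def brute_pair_filter(ann, cds_len_bounds=(100, 10_000), intergenic_bounds=(50, 10_000)):
    """All qualifying gene pairs by literal application of the four filters.

    Returns {'OR': set of 'up|down' ids, 'nonOR': ...}.
    """
    out = {"OR": set(), "nonOR": set()}
    genes = list(ann.genes.values())
    for a, b in combinations(genes, 2):
        if a.start > b.start or (a.start == b.start and a.end > b.end):
            a, b = b, a
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        if not (cds_len_bounds[0] <= a.cds_length <= cds_len_bounds[1]):
            continue
        if not (cds_len_bounds[0] <= b.cds_length <= cds_len_bounds[1]):
            continue
        gap = b.start - a.end
        if not (intergenic_bounds[0] <= gap <= intergenic_bounds[1]):
            continue
        if any(
            g.chrom == a.chrom and g.start < b.end and a.start < g.end
            for g in genes
            if g.gene_id not in (a.gene_id, b.gene_id)
        ):
            continue
        if a.biotype == "OR" and b.biotype == "OR":
            cls = "OR"
        elif a.biotype != "OR" and b.biotype != "OR":
            cls = "nonOR"
        else:
            continue
        up, down = (a, b) if a.strand == "+" else (b, a)
        out[cls].add(f"{up.gene_id}|{down.gene_id}")
    return out


def brute_flanking(target_span, ref_strand, member_ids, genes):
    """Exhaustive nearest-non-OR scan for each flanking slot."""
    slots = {k: None for k in
             ("upstream_same", "upstream_opposite", "downstream_same", "downstream_opposite")}
    best = {}
    for g in genes:
        if g.biotype == "OR" or g.gene_id in member_ids:
            continue
        if g.end <= target_span[0]:
            side, dist = "left", target_span[0] - g.end
        elif g.start >= target_span[1]:
            side, dist = "right", g.start - target_span[1]
        else:
            continue
        if ref_strand == "+":
            where = "upstream" if side == "left" else "downstream"
        else:
            where = "downstream" if side == "left" else "upstream"
        rel = "same" if g.strand == ref_strand else "opposite"
        key = f"{where}_{rel}"
        if key not in best or dist < best[key][0]:
            best[key] = (dist, g)
    for key, (_, g) in best.items():
        slots[key] = g
    return slots


def brute_mean_coverage(arr, intervals):
    """Per-base mean over the union of intervals via an explicit base set."""
    bases = sorted({p for s, e in intervals for p in range(s, e)})
    return sum(float(arr[p]) for p in bases) / len(bases)


def exact_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties assumed)."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    observed = u_stat(a, b)
    mean_u = len(a) * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def t_ci(values, confidence=0.95):
    """Closed-form t confidence interval (textbook formula)."""
    from scipy.stats import t as tdist

    x = np.asarray(values, float)
    n = len(x)
    m = x.mean()
    s = x.std(ddof=1)
    half = tdist.ppf(0.5 + confidence / 2.0, n - 1) * s / np.sqrt(n)
    return m - half, m + half
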