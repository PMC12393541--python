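"""Single-nucleus expression analysis of chosen-OR selectivity.

Each olfactory sensory neuron expresses one *chosen* OR at high level; ORs
downstream of it in the same tandem array are co-expressed at low,
nuclear-retained levels (the staircase pattern), and an antisense lncRNA
from the chosen promoter suppresses the OR immediately upstream. These
routines operate on an :class:`anndata.AnnData` of raw UMI counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as scpy
from scipy import sparse, stats

from orgate.annotation import GenomeAnnotation, TandemArray

logger = logging.getLogger(__name__)

DISTANCE_BINS = ((0.0, 2500.0), (2500.0, 5000.0), (5000.0, 10000.0))


def _dense_col(adata: ad.AnnData, gene: str) -> np.ndarray:
    x = adata[:, gene].X
    return np.asarray(x.todense()).ravel() if sparse.issparse(x) else np.asarray(x).ravel()


def filter_neurons(
    adata: ad.AnnData,
    markers: list[str],
    min_markers: int = 2,
    min_umi: int = 2,
) -> ad.AnnData:
    """Keep cells with >= ``min_markers`` neuron markers at UMI >= ``min_umi``."""
    present = [m for m in markers if m in adata.var_names]
    missing = set(markers) - set(present)
    if missing:
        logger.warning("markers absent from matrix: %s", sorted(missing))
    if not present:
        raise ValueError("none of the marker genes are present in the matrix")
    X = adata[:, present].X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    keep = (X >= min_umi).sum(axis=1) >= min_markers
    return adata[np.asarray(keep).ravel()].copy()


def normalize(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Per-cell scaling to ``target_sum`` total counts, then natural log1p.

    Empty cells stay all-zero. The normalization parameters are recorded in
    ``.uns['normalization']`` so the exp-sum identity can be re-checked.
    """
    nm = adata.copy()
    scpy.pp.normalize_total(nm, target_sum=target_sum)
    scpy.pp.log1p(nm)
    nm.uns["normalization"] = {"target_sum": target_sum, "log_base": "e"}
    return nm


@dataclass
class ChosenOR:
    cell_id: str
    chosen_or: str | None
    chosen_value: float
    array_id: str | None  # array id or 'singleton'; None when no OR expressed
    tie_flag: bool


def assign_chosen_or(
    nm: ad.AnnData,
    or_genes: list[str],
    arrays: list[TandemArray] | None = None,
    ann: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """Per-cell argmax over OR columns of the normalized matrix.

    Ties are broken toward the lowest genomic coordinate (requires ``ann``)
    and flagged; cells with no OR signal get ``chosen_or=None``. Array
    context is attached when ``arrays`` is given.
    """
    present = [g for g in or_genes if g in nm.var_names]
    if not present:
        raise ValueError("no OR genes present in the matrix")
    if ann is not None:
        present = sorted(present, key=lambda g: (ann[g].chrom, ann[g].start))
    X = nm[:, present].X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    arr_of = {}
    if arrays:
        for a in arrays:
            for oid in a.or_ids:
                arr_of[oid] = a.array_id
    rows = []
    for i, cell in enumerate(nm.obs_names):
        vals = X[i]
        best = float(vals.max()) if len(vals) else 0.0
        if best <= 0:
            rows.append(ChosenOR(cell, None, 0.0, None, False))
            continue
        winners = np.flatnonzero(vals == best)
        gene = present[winners[0]]  # lowest genomic coordinate wins ties
        rows.append(
            ChosenOR(cell, gene, best, arr_of.get(gene, "singleton"), len(winners) > 1)
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("cell_id")


def staircase_matrix(
    array: TandemArray,
    nm: ad.AnnData,
    chosen: pd.DataFrame,
    ann: GenomeAnnotation,
    lnc_filter: str | None = None,
    lnc_detectable: bool = True,
) -> pd.DataFrame:
    """Cells (sorted by chosen-OR genomic position) x array ORs (genomic order).

    Rows are restricted to cells whose chosen OR is in the array; with
    ``lnc_filter`` set, further restricted to cells where that lncRNA is
    detectable (>0) or absent, per ``lnc_detectable``.
    """
    order = sorted(array.or_ids, key=lambda g: ann[g].start)
    cells = chosen[chosen["chosen_or"].isin(array.or_ids)]
    if lnc_filter is not None:
        lnc_vals = pd.Series(_dense_col(nm, lnc_filter), index=nm.obs_names)
        mask = lnc_vals.loc[cells.index] > 0
        cells = cells[mask if lnc_detectable else ~mask]
    if cells.empty:
        logger.warning("staircase: no cells with a chosen OR in %s", array.array_id)
        return pd.DataFrame(columns=order)
    pos = {g: ann[g].start for g in array.or_ids}
    cells = cells.sort_values("chosen_or", key=lambda s: s.map(pos), kind="stable")
    sub = nm[cells.index, order].X
    sub = sub.toarray() if sparse.issparse(sub) else np.asarray(sub)
    return pd.DataFrame(sub, index=cells.index, columns=order)


def flanking_enrichment(
    groups: dict[str, list[str]],
    flank_map: dict[str, str | None],
    nm: ad.AnnData,
) -> pd.DataFrame:
    """Dot-matrix summary: per (cell group, flanking gene) detection and level.

    ``groups`` maps array id -> cell ids (from chosen-OR assignment);
    ``flank_map`` maps array id -> flanking gene id (or None). Output rows
    are (group, gene, pct_detected, mean_lognorm).
    """
    rows = []
    for array_id, cells in groups.items():
        for target_id, gene in flank_map.items():
            if gene is None or gene not in nm.var_names:
                if gene is not None:
                    logger.warning("flanking gene %s absent from matrix", gene)
                rows.append(
                    {"group": array_id, "target": target_id, "gene": gene,
                     "pct_detected": 0.0, "mean_lognorm": 0.0}
                )
                continue
            vals = pd.Series(_dense_col(nm, gene), index=nm.obs_names).loc[cells]
            rows.append(
                {
                    "group": array_id,
                    "target": target_id,
                    "gene": gene,
                    "pct_detected": 100.0 * float((vals > 0).mean()) if len(vals) else 0.0,
                    "mean_lognorm": float(vals.mean()) if len(vals) else 0.0,
                }
            )
    return pd.DataFrame(rows)


def lnc_neighbor_coexpression(
    lnc_id: str,
    array: TandemArray,
    nm: ad.AnnData,
    ann: GenomeAnnotation,
) -> pd.DataFrame:
    """Mean OR expression among cells detectably expressing a nested lncRNA.

    For every OR in the array, reports the TSS-to-TSS distance from the
    lncRNA and the mean normalized value over lncRNA-positive (>0) cells,
    with the OR labeled upstream/downstream of the lncRNA TSS in the
    array's transcription direction.
    """
    lnc_vals = _dense_col(nm, lnc_id)
    expressing = np.flatnonzero(lnc_vals > 0)
    if len(expressing) == 0:
        return pd.DataFrame(columns=["or_id", "tss_distance", "side", "mean_lognorm"])
    lnc_tss = ann[lnc_id].tss
    sgn = 1 if array.majority_strand == "+" else -1
    rows = []
    for oid in array.or_ids:
        if oid not in nm.var_names:
            continue
        vals = _dense_col(nm, oid)[expressing]
        d = ann[oid].tss - lnc_tss
        rows.append(
            {
                "or_id": oid,
                "tss_distance": abs(d),
                "side": "upstream" if sgn * d <= 0 else "downstream",
                "mean_lognorm": float(vals.mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LncPartner:
    """One qualifying (chosen OR, antisense lncRNA) promoter pairing.

    ``distance`` is from the OR TSS to the lncRNA 3' end; ``upstream_or`` /
    ``downstream_or`` are the array neighbors flanking the chosen OR in its
    transcription direction.
    """

    lnc_id: str
    chosen_or: str
    upstream_or: str | None
    downstream_or: str | None
    distance: float


def find_lnc_partners(
    ann: GenomeAnnotation,
    arrays: list[TandemArray],
    max_distance: float = 10_000.0,
) -> list[LncPartner]:
    """Pair each chosen-OR candidate with its nearest upstream antisense lncRNA.

    A lncRNA qualifies for an OR when it lies on the opposite strand and its
    3' end is within ``max_distance`` upstream of the OR TSS (the two share a
    bidirectional promoter region). Array neighbors are assigned in the OR's
    transcription direction.
    """
    out = []
    for a in arrays:
        order = sorted(a.or_ids, key=lambda g: ann[g].start)
        for idx, oid in enumerate(order):
            g = ann[oid]
            sgn = 1 if g.strand == "+" else -1
            prev_i, next_i = (idx - 1, idx + 1) if g.strand == "+" else (idx + 1, idx - 1)
            upstream = order[prev_i] if 0 <= prev_i < len(order) else None
            downstream = order[next_i] if 0 <= next_i < len(order) else None
            best = None
            for lnc in ann.lncrnas:
                if lnc.chrom != g.chrom or lnc.strand == g.strand:
                    continue
                d = sgn * (g.tss - lnc.three_prime)
                if 0 <= d <= max_distance and (best is None or d < best[1]):
                    best = (lnc.gene_id, d)
            if best is not None:
                out.append(LncPartner(best[0], oid, upstream, downstream, float(best[1])))
    return out


@dataclass
class LncCorrelationRecord:
    lncrna_id: str
    partner_role: str  # {'upstream_OR', 'chosen_OR', 'downstream_OR'}
    n_cells: int
    pearson_r: float
    p_value: float
    distance_bin: str


def _bin_label(d: float, bins=DISTANCE_BINS) -> str | None:
    for lo, hi in bins:
        if (lo < d <= hi) or (lo == 0.0 and d == 0.0):
            return f"({lo / 1000:g},{hi / 1000:g}] kbp" if lo > 0 else f"[0,{hi / 1000:g}] kbp"
    return None


def lnc_or_correlation(
    nm: ad.AnnData,
    chosen: pd.DataFrame,
    partners: list[LncPartner],
    min_cells: int = 3,
    pooled: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of lncRNA vs flanking-OR expression across cells.

    Cells are grouped by their chosen OR; each qualifying chosen OR
    contributes its cells with the paired lncRNA's values. With
    ``pooled=True`` cells are pooled per distance bin across chosen ORs
    (scatterplot style); otherwise one record per (lncRNA, role). Constant
    vectors and groups below ``min_cells`` are skipped.
    """
    pieces: dict[tuple[str, str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    for p in partners:
        cells = chosen.index[chosen["chosen_or"] == p.chosen_or]
        if len(cells) < min_cells or p.lnc_id not in nm.var_names:
            continue
        binlab = _bin_label(p.distance)
        if binlab is None:
            continue
        idx = nm.obs_names.get_indexer(cells)
        lnc_vals = _dense_col(nm, p.lnc_id)[idx]
        for role, gene in (
            ("upstream_OR", p.upstream_or),
            ("chosen_OR", p.chosen_or),
            ("downstream_OR", p.downstream_or),
        ):
            if gene is None or gene not in nm.var_names:
                continue
            key = (p.lnc_id, role, binlab) if not pooled else ("pooled", role, binlab)
            pieces.setdefault(key, []).append((lnc_vals, _dense_col(nm, gene)[idx]))
    rows = []
    for (lnc_id, role, binlab), chunks in sorted(pieces.items()):
        x = np.concatenate([c[0] for c in chunks])
        y = np.concatenate([c[1] for c in chunks])
        if len(x) < min_cells or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p_val = stats.pearsonr(x, y)
        rows.append(
            LncCorrelationRecord(
                lncrna_id=lnc_id, partner_role=role, n_cells=len(x),
                pearson_r=float(r), p_value=float(p_val), distance_bin=binlab,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def per_lnc_mean_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """Mean per-lncRNA correlation per role, with a one-sample t-test vs 0."""
    rows = []
    for role, sub in records.groupby("partner_role"):
        rs = sub["pearson_r"].to_numpy(float)
        row = {"partner_role": role, "n_lnc": len(rs), "mean_r": float(rs.mean())}
        if len(rs) >= 2 and np.ptp(rs) > 0:
            t, p = stats.ttest_1samp(rs, 0.0)
            row.update(t_stat=float(t), p_value=float(p))
        else:
            row.update(t_stat=np.nan, p_value=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def switch_fraction(
    nm: ad.AnnData,
    cells: list[str],
    lnc_id: str,
    upstream_or: str,
    detect_thresh: float = 0.0,
) -> float:
    """Fraction of cells with mutually exclusive lncRNA / upstream-OR detection.

    Measures the switch-like regime: exactly one of the two transcripts is
    above ``detect_thresh``.
    """
    if not len(cells):
        raise ValueError("switch_fraction needs at least one cell")
    idx = nm.obs_names.get_indexer(cells)
    a = _dense_col(nm, lnc_id)[idx] > detect_thresh
    b = _dense_col(nm, upstream_or)[idx] > detect_thresh
    return float(np.mean(a ^ b))
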