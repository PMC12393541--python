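"""End-to-end workflows on synthetic data, one per figure-family computation.

Each workflow generates its inputs with the seeded generators, runs the
corresponding analysis stages, writes plain-text tables stamped with the
resolved-config hash, and returns a summary dict of the headline numbers.
``demo`` chains every workflow.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from orgate import annotation, coverage, fishquant, sc, synthetic, tss
from orgate.config import config_hash, load_config, save_config

logger = logging.getLogger(__name__)

WORKFLOWS = ("readthrough", "antisense", "tss", "staircase", "lnc_correlation", "fish", "demo")


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _coverage_inputs(cfg: dict, seed: int):
    # each OR pair is its own two-gene transcription unit, so the per-pair
    # readthrough expectation stays in closed form (no stacked deposits)
    syn = cfg["synth"]
    n_pairs = cfg["coverage"]["n_pairs"]
    ann, arrays, truth = synthetic.gen_annotation(
        seed=seed,
        n_arrays=n_pairs,
        array_size_range=(2, 2),
        gene_len=syn["gene_len"],
        gap_range=tuple(syn["gap_range"]),
        inversion_rate=0.0,
        lnc_per_array=0,
        flank_genes=False,
        n_nonor_pairs=n_pairs,
    )
    a = cfg["annotation"]
    or_pairs, nonor_pairs = annotation.sample_gene_pairs(
        ann,
        cds_len_bounds=tuple(a["cds_len_bounds"]),
        intergenic_bounds=tuple(a["intergenic_bounds"]),
        seed=seed,
    )
    return ann, or_pairs, nonor_pairs


def _relcov_records(ann, pairs, cfg, seed, antisense_fraction=None):
    cov = cfg["coverage"]
    track = synthetic.gen_coverage(
        ann,
        pairs,
        promoter_rate=cov["promoter_rate"],
        readthrough_decay_per_kb=cov["readthrough_decay_per_kb"],
        nonor_decay_per_kb=cov["nonor_decay_per_kb"],
        antisense_fraction=(
            cov["antisense_fraction"] if antisense_fraction is None else antisense_fraction
        ),
        nonor_antisense_fraction=cov["nonor_antisense_fraction"],
        seed=seed,
    )
    records = [r for p in pairs for r in coverage.pair_relative_coverage(p, track)]
    return track, records


def run_readthrough(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    ann, or_pairs, nonor_pairs = _coverage_inputs(cfg, seed)
    _, records = _relcov_records(ann, or_pairs + nonor_pairs, cfg, seed)
    df = coverage.records_frame(records)
    _write_table(df, outdir / "relative_coverage.tsv", config_hash(cfg))
    or_recs = [r for r in records if r.pair_class == "OR"]
    nonor_recs = [r for r in records if r.pair_class == "nonOR"]
    stats = coverage.compare_groups(or_recs, nonor_recs, features=("intergenic",))
    _write_table(stats, outdir / "readthrough_tests.tsv", config_hash(cfg))

    def med(recs):
        vals = [
            r.rel_cov
            for r in recs
            if r.feature == "intergenic" and r.orientation == "sense" and r.rel_cov is not None
        ]
        return float(np.median(vals)) if vals else float("nan")

    return {
        "n_or_pairs": len(or_pairs),
        "n_nonor_pairs": len(nonor_pairs),
        "median_intergenic_relcov_or": med(or_recs),
        "median_intergenic_relcov_nonor": med(nonor_recs),
        "intergenic_ranksum_p": float(stats["p_raw"].iloc[0]) if len(stats) else float("nan"),
    }


def run_antisense(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    ann, or_pairs, nonor_pairs = _coverage_inputs(cfg, seed)
    _, records = _relcov_records(ann, or_pairs + nonor_pairs, cfg, seed)
    df = coverage.records_frame(records)
    _write_table(
        df[df["orientation"] == "antisense"], outdir / "antisense_coverage.tsv", config_hash(cfg)
    )

    def med(recs, cls):
        vals = [
            r.rel_cov
            for r in recs
            if r.pair_class == cls
            and r.feature == "upstream_exons"
            and r.orientation == "antisense"
            and r.rel_cov is not None
        ]
        return float(np.median(vals)) if vals else float("nan")

    return {
        "median_antisense_relcov_or": med(records, "OR"),
        "median_antisense_relcov_nonor": med(records, "nonOR"),
        "antisense_fraction_true": cfg["coverage"]["antisense_fraction"],
    }


def run_tss(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    syn, tcfg = cfg["synth"], cfg["tss"]
    ann, arrays, truth = synthetic.gen_annotation(
        seed=seed,
        n_arrays=syn["n_arrays"],
        array_size_range=tuple(syn["array_size_range"]),
        lnc_per_array=0,
    )
    genes = ann.ors
    anchors = {g.gene_id: annotation.anchor_tss(g, "first_cds") for g in genes}
    track, bidir_truth = synthetic.gen_tss(
        ann,
        genes,
        anchors,
        sense_offset=tuple(tcfg["sense_offset"]),
        antisense_offset=tuple(tcfg["antisense_offset"]),
        reads_per_gene=tcfg["reads_per_gene"],
        bidir_fraction=tcfg["bidir_fraction"],
        window_bp=tcfg["window_bp"],
        seed=seed,
    )
    results = tss.window_assign(
        track, genes, anchors, window_bp=tcfg["window_bp"], min_reads=tcfg["min_reads"]
    )
    _write_table(tss.results_frame(results), outdir / "promoter_windows.tsv", config_hash(cfg))
    frac = tss.bidirectional_fraction(results)
    sense_med = tss.median_offset(results, "sense")
    anti_med = tss.median_offset(results, "antisense")
    return {
        "n_genes": len(genes),
        "bidirectional_fraction": frac,
        "bidirectional_fraction_true": sum(bidir_truth.values()) / len(bidir_truth),
        "sense_median_offset_bp": sense_med,
        "antisense_median_offset_bp": anti_med,
        "offset_delta_bp": anti_med - sense_med,
    }


def _counts_inputs(cfg: dict, seed: int):
    syn, s = cfg["synth"], cfg["sc"]
    ann, arrays, truth = synthetic.gen_annotation(
        seed=seed,
        n_arrays=syn["n_arrays"],
        array_size_range=tuple(syn["array_size_range"]),
        lnc_per_array=syn["lnc_per_array"],
    )
    adata, cell_truth = synthetic.gen_counts(
        ann,
        arrays,
        truth,
        n_cells=s["n_cells"],
        chosen_mean=s["chosen_mean"],
        downstream_decay=s["downstream_decay"],
        lnc_mean=s["lnc_mean"],
        leak_mean=s["leak_mean"],
        lnc_coupling=s["lnc_coupling"],
        nb_dispersion=s["nb_dispersion"],
        seed=seed,
    )
    return ann, arrays, truth, adata, cell_truth


def run_staircase(cfg: dict, outdir: Path) -> dict:
    seed, s = cfg["seed"], cfg["sc"]
    ann, arrays, truth, adata, cell_truth = _counts_inputs(cfg, seed)
    filtered = sc.filter_neurons(
        adata, synthetic.MARKER_GENES, min_markers=s["min_markers"], min_umi=s["min_umi"]
    )
    nm = sc.normalize(filtered, target_sum=s["target_sum"])
    or_ids = [g.gene_id for g in ann.ors]
    chosen = sc.assign_chosen_or(nm, or_ids, arrays, ann)
    _write_table(chosen.reset_index(), outdir / "chosen_or.tsv", config_hash(cfg))
    joined = chosen.join(cell_truth)
    recovery = float((joined["chosen_or"] == joined["chosen_promoter"]).mean())
    stair = sc.staircase_matrix(arrays[0], nm, chosen, ann)
    stair.to_csv(outdir / "staircase_array1.tsv", sep="\t")
    return {
        "n_cells_after_filter": int(nm.n_obs),
        "chosen_or_recovery": recovery,
        "staircase_cells_array1": int(len(stair)),
    }


def run_lnc_correlation(cfg: dict, outdir: Path) -> dict:
    seed, s = cfg["seed"], cfg["sc"]
    # correlation-study conditions: one nested lncRNA per small array,
    # sample conditioned on cells whose chosen OR has a nearby upstream lncRNA
    ann, arrays, truth = synthetic.gen_annotation(
        seed=seed,
        n_arrays=s["corr_n_lncrnas"],
        array_size_range=(3, 4),
        lnc_per_array=1,
    )
    adata, cell_truth = synthetic.gen_counts(
        ann,
        arrays,
        truth,
        n_cells=s["corr_n_cells"],
        chosen_mean=s["chosen_mean"],
        downstream_decay=s["downstream_decay"],
        lnc_mean=s["lnc_mean"],
        leak_mean=s["leak_mean"],
        lnc_coupling=s["lnc_coupling"],
        nb_dispersion=s["nb_dispersion"],
        partner_bias=s["partner_bias"],
        seed=seed,
    )
    nm = sc.normalize(
        sc.filter_neurons(adata, synthetic.MARKER_GENES, s["min_markers"], s["min_umi"]),
        target_sum=s["target_sum"],
    )
    or_ids = [g.gene_id for g in ann.ors]
    chosen = sc.assign_chosen_or(nm, or_ids, arrays, ann)
    partners = sc.find_lnc_partners(ann, arrays)
    per_lnc = sc.lnc_or_correlation(nm, chosen, partners, min_cells=s["min_cells"], pooled=False)
    _write_table(per_lnc, outdir / "lnc_correlations.tsv", config_hash(cfg))
    # per-lncRNA summary restricted to lncRNAs with 3' end within 5 kbp
    close = per_lnc[per_lnc["distance_bin"].isin(["[0,2.5] kbp", "(2.5,5] kbp"])]
    summary = sc.per_lnc_mean_correlation(close)
    _write_table(summary, outdir / "lnc_correlation_summary.tsv", config_hash(cfg))
    out = {"n_partners": len(partners), "n_lnc_records": int(len(per_lnc))}
    for _, row in summary.iterrows():
        role = row["partner_role"].replace("_OR", "").lower()
        out[f"mean_r_{role}"] = float(row["mean_r"])
        out[f"p_{role}"] = float(row["p_value"])
    # switch-like regime among close-promoter partners
    fracs = []
    for p in partners:
        if p.distance > 2500 or p.upstream_or is None:
            continue
        cells = chosen.index[chosen["chosen_or"] == p.chosen_or].tolist()
        if cells:
            fracs.append(sc.switch_fraction(nm, cells, p.lnc_id, p.upstream_or))
    if fracs:
        out["switch_fraction"] = float(np.mean(fracs))
    return out


def run_fish(cfg: dict, outdir: Path) -> dict:
    seed, f = cfg["seed"], cfg["fish"]
    stack, labels, truths = synthetic.gen_stack(
        seed=seed,
        shape=tuple(f["shape"]),
        n_cells=f["n_cells"],
        dapi_attenuation=f["dapi_attenuation"],
        noise=f["noise"],
    )
    thresholds = {
        "nuclear_signal": f["nuclear_signal"],
        "cytoplasmic_signal": f["cytoplasmic_signal"],
        "nuclear_area": tuple(f["nuclear_area"]),
        "cytoplasmic_area": f["cytoplasmic_area"],
        "eccentricity": f["eccentricity"],
    }
    records, classes = fishquant.classify_cells(
        stack,
        labels,
        sigma=f["sigma"],
        min_area=f["min_area"],
        dilate_px=f["dilate_px"],
        q_low=f["q_low"],
        q_high=f["q_high"],
        thresholds=thresholds,
    )
    rows = []
    truth_by_id = {(t.z, t.cell_id): t.cell_class for t in truths}
    hits = 0
    for rec in records:
        true_cls = truth_by_id.get(rec.roi_id)
        pred = classes[rec.roi_id]
        hits += pred == true_cls
        rows.append(
            {
                "slice": rec.roi_id[0],
                "label": rec.roi_id[1],
                "nuclear_area": rec.nuclear_area,
                "eccentricity": rec.eccentricity,
                "norm_nuclear": rec.norm_nuclear.get(1),
                "norm_cytoplasmic": rec.norm_cytoplasmic.get(1),
                "predicted": pred,
                "truth": true_cls,
            }
        )
    _write_table(pd.DataFrame(rows), outdir / "fish_rois.tsv", config_hash(cfg))
    return {
        "n_rois": len(records),
        "class_accuracy": hits / len(records) if records else float("nan"),
    }


RUNNERS = {
    "readthrough": run_readthrough,
    "antisense": run_antisense,
    "tss": run_tss,
    "staircase": run_staircase,
    "lnc_correlation": run_lnc_correlation,
    "fish": run_fish,
}


def run_workflow(name: str, cfg: dict | None = None, outdir: str | Path = "orgate_out") -> dict:
    """Run one named workflow (or ``demo`` = all) and write its output bundle.

    The resolved config is saved next to the outputs; on failure a FAILED
    marker file is left so partial outputs are never mistaken for results.
    """
    if name not in WORKFLOWS:
        raise ValueError(f"unknown workflow {name!r}; choose from {WORKFLOWS}")
    cfg = cfg if cfg is not None else load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, str(outdir / "resolved_config.yaml"))
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        t0 = time.time()
        if name == "demo":
            summary = {}
            for wf in RUNNERS:
                sub = outdir / wf
                sub.mkdir(exist_ok=True)
                t1 = time.time()
                summary[wf] = RUNNERS[wf](cfg, sub)
                logger.info("workflow %s finished in %.1fs", wf, time.time() - t1)
        else:
            summary = RUNNERS[name](cfg, outdir)
        summary_out = {
            "workflow": name,
            "seed": cfg["seed"],
            "config_hash": config_hash(cfg),
            "elapsed_s": round(time.time() - t0, 2),
            "results": summary,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary_out, fh, indent=2)
        return summary
    except Exception:
        marker.write_text("workflow failed; outputs in this directory are partial\n")
        raise
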