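"""End-to-end orchestration: simulate -> QC -> cluster -> markers ->
identity -> GSEA, plus the metabolomics and bioenergetics branches.

A single global seed is fanned out to per-stage child seeds by fixed
offsets so each stage is independently reproducible; identical seeds give
byte-identical on-disk outputs. Wall-clock timings go to the run log only,
keeping report.json deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioenergetics as be
from . import cipr, clustering, gsea as gsea_mod, io, metabolomics as metab, qc
from .markers import find_markers
from .simulate import SimulationConfig, decoy_gene_sets, simulate_bead_counts, \
    simulate_counts, simulate_ecar_trace, simulate_metabolites, make_reference

logger = logging.getLogger("myomac")

# fixed per-stage seed offsets (stage seeds = global seed + offset)
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "cluster": 101,
    "gsea": 202,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {},  # overrides for SimulationConfig fields
    "qc": {
        "mito_low": qc.DEFAULT_MITO_LOW,
        "mito_high": qc.DEFAULT_MITO_HIGH,
        "min_counts": qc.DEFAULT_MIN_COUNTS,
        "n_hvg": 1000,
    },
    "clustering": {
        "n_pcs": 20,
        "k": clustering.DEFAULT_K,
        "prune": clustering.DEFAULT_PRUNE,
        "resolution": clustering.DEFAULT_RESOLUTION,
    },
    "markers": {
        "min_pct": 0.1,
        "min_abs_logratio": 0.25,
    },
    "cipr": {
        "alpha": 0.05,
        "top_n": None,
    },
    "gsea": {
        "n_perm": 1000,
        "weight": 1.0,
        "n_decoy_sets": 10,
    },
    "metabolomics": {
        "fc_cut": metab.DEFAULT_FC_CUT,
        "p_cut": metab.DEFAULT_P_CUT,
        "glog_lambda": None,
    },
    "bioenergetics": {
        "aggregation": "max",
        "normalize_protein": False,
    },
}

_RANGES = {
    ("qc", "mito_low"): (0.0, 1.0),
    ("qc", "mito_high"): (0.0, 1.0),
    ("qc", "min_counts"): (0, None),
    ("qc", "n_hvg"): (1, None),
    ("clustering", "n_pcs"): (1, None),
    ("clustering", "k"): (1, None),
    ("clustering", "prune"): (0.0, 1.0),
    ("clustering", "resolution"): (0.0, None),
    ("markers", "min_pct"): (0.0, 1.0),
    ("markers", "min_abs_logratio"): (0.0, None),
    ("cipr", "alpha"): (0.0, 1.0),
    ("gsea", "n_perm"): (100, None),
    ("gsea", "weight"): (0.0, None),
    ("gsea", "n_decoy_sets"): (0, None),
    ("metabolomics", "fc_cut"): (1.0, None),
    ("metabolomics", "p_cut"): (0.0, 1.0),
}

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclasses.dataclass
class PipelineConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed + STAGE_SEED_OFFSETS["simulate"],
                                **self.raw["simulation"])


def _merge(defaults: dict, overrides: dict, path: str, errors: list[str]) -> dict:
    out = {}
    for key, val in defaults.items():
        if key in overrides and isinstance(val, dict) and isinstance(overrides[key], dict):
            out[key] = _merge(val, overrides[key], f"{path}{key}.", errors)
        elif key in overrides:
            out[key] = overrides[key]
        else:
            out[key] = val
    for key in overrides:
        if key not in defaults:
            errors.append(f"unknown config key {path}{key!r}")
    return out


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults, reject unknown keys, range-check stage parameters.

    All violations are reported together in one error.
    """
    errors: list[str] = []
    raw = dict(raw) if raw else {}
    # simulation block is validated against SimulationConfig fields, not
    # against defaults (its defaults live on the dataclass itself)
    sim = dict(raw.pop("simulation", {}) or {})
    for key in sim:
        if key not in _SIM_FIELDS or key == "seed":
            errors.append(f"unknown config key simulation.{key!r}")
    merged = _merge(DEFAULT_CONFIG, raw, "", errors)
    merged["simulation"] = sim
    for (section, key), (lo, hi) in _RANGES.items():
        val = merged[section][key]
        if val is None:
            continue
        if lo is not None and val < lo:
            errors.append(f"{section}.{key} = {val} below minimum {lo}")
        if hi is not None and val > hi:
            errors.append(f"{section}.{key} = {val} above maximum {hi}")
    if merged["qc"]["mito_low"] >= merged["qc"]["mito_high"]:
        errors.append("qc.mito_low must be < qc.mito_high")
    if merged["bioenergetics"]["aggregation"] not in {"max", "mean"}:
        errors.append("bioenergetics.aggregation must be 'max' or 'mean'")
    if not isinstance(merged["seed"], int):
        errors.append("seed must be an integer")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(merged)


def _df_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage, write all outputs under ``outdir``, return the
    run report (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": config.raw, "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = dt
                if exc_type is not None:
                    logger.error("stage %s: failed after %.2fs", name, dt)
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                logger.info("stage %s: done in %.2fs", name, dt)

        return _Timer()

    # --- simulate -----------------------------------------------------------
    with stage("simulate"):
        sim_cfg = config.simulation_config()
        ref = make_reference(sim_cfg)
        counts, metadata, truth = simulate_counts(ref, sim_cfg)
        io.write_mtx_triplet(counts, outdir / "counts")
        _df_tsv(metadata, outdir / "cell_metadata.tsv")
        ref.values.to_csv(outdir / "reference_panel.tsv", sep="\t")
        truth_df = pd.DataFrame({
            "barcode": truth.cell_types.index,
            "true_type": truth.cell_types.to_numpy(),
            "qc_outlier": truth.qc_outliers.to_numpy(),
        })
        _df_tsv(truth_df, outdir / "ground_truth_cells.tsv")
        sets = decoy_gene_sets(
            [g for g in counts.gene_ids if g not in set(truth.mito_genes)],
            truth.enriched_sets,
            n_decoys=config["gsea"]["n_decoy_sets"],
            seed=config.seed + STAGE_SEED_OFFSETS["gsea"],
        )
        io.write_gmt(sets, outdir / "gene_sets.gmt")
        report["stages"]["simulate"] = {
            "n_cells": counts.n_cells, "n_genes": counts.n_genes,
            "n_samples": len(sim_cfg.samples),
            "n_planted_outliers": int(truth.qc_outliers.sum()),
        }

    # --- QC + normalization -------------------------------------------------
    with stage("qc"):
        qc_cfg = config["qc"]
        qc_df = qc.compute_qc(counts, truth.mito_genes, qc_cfg["mito_low"],
                              qc_cfg["mito_high"], qc_cfg["min_counts"])
        _df_tsv(qc_df, outdir / "qc_report.tsv")
        filtered = qc.filter_cells(counts, qc_df, qc_cfg["mito_low"],
                                   qc_cfg["mito_high"], qc_cfg["min_counts"])
        expr = qc.log_normalize(filtered)
        hvg = qc.select_hvg(expr, n_top=min(qc_cfg["n_hvg"], expr.n_genes))
        (outdir / "hvg.tsv").write_text("".join(g + "\n" for g in hvg.genes))
        report["stages"]["qc"] = {
            "cells_in": counts.n_cells,
            "cells_out": filtered.n_cells,
            "cells_removed": counts.n_cells - filtered.n_cells,
            "n_hvg": len(hvg.genes),
        }

    # --- clustering ----------------------------------------------------------
    with stage("cluster"):
        cl_cfg = config["clustering"]
        pca = clustering.pca_embed(expr, hvg.genes, n_pcs=cl_cfg["n_pcs"])
        knn = clustering.knn_graph(pca.coords, k=cl_cfg["k"])
        snn = clustering.snn_from_knn(knn, prune=cl_cfg["prune"])
        assignment = clustering.modularity_cluster(
            snn, resolution=cl_cfg["resolution"],
            seed=config.seed + STAGE_SEED_OFFSETS["cluster"])
        clusters_df = pd.DataFrame({"barcode": expr.barcodes,
                                    "cluster": assignment.labels})
        _df_tsv(clusters_df, outdir / "clusters.tsv")
        report["stages"]["cluster"] = {
            "cells": expr.n_cells,
            "n_clusters": assignment.n_clusters,
            "modularity": round(float(assignment.modularity), 10),
        }

    # --- markers -------------------------------------------------------------
    with stage("markers"):
        mk_cfg = config["markers"]
        result = find_markers(
            expr, assignment.labels,
            min_pct=mk_cfg["min_pct"], min_abs_logratio=mk_cfg["min_abs_logratio"])
        all_sig = []
        for sig in result.signatures:
            t = sig.table.copy()
            t.insert(0, "cluster", sig.cluster)
            all_sig.append(t)
        _df_tsv(pd.concat(all_sig, ignore_index=True), outdir / "marker_signatures.tsv")
        report["stages"]["markers"] = {
            "clusters_tested": len(result.signatures),
            "clusters_excluded": len(result.excluded_clusters),
            "genes_tested_total": int(sum(len(s.table) for s in result.signatures)),
        }

    # --- identity scoring ----------------------------------------------------
    with stage("identify"):
        ci_cfg = config["cipr"]
        ratios = cipr.reference_log_ratios(ref)
        score_table = cipr.identity_scores(result.signatures, ratios,
                                           alpha=ci_cfg["alpha"], top_n=ci_cfg["top_n"])
        score_table.scores.to_csv(outdir / "identity_scores.tsv", sep="\t",
                                  float_format="%.10g")
        _df_tsv(score_table.assignments, outdir / "identity_assignments.tsv")
        # score against ground truth: majority true type per cluster
        truth_types = truth.cell_types.loc[expr.barcodes].to_numpy()
        correct = 0
        gen_types = {}
        for _, row in score_table.assignments.iterrows():
            members = assignment.labels == row["cluster"]
            gen = pd.Series(truth_types[members]).mode().iloc[0]
            gen_types[row["cluster"]] = gen
            if row["identity"] == gen:
                correct += 1
        accuracy = correct / len(score_table.assignments)
        report["stages"]["identify"] = {
            "n_clusters": len(score_table.assignments),
            "identity_accuracy_vs_truth": round(accuracy, 6),
            "n_flagged": int((score_table.assignments["flag"] != "ok").sum()),
        }

    # --- GSEA (young vs old macrophage cells) --------------------------------
    with stage("gsea"):
        gs_cfg = config["gsea"]
        assigned = score_table.assignments.set_index("cluster")["identity"]
        macro_clusters = [c for c, ident in assigned.items()
                          if str(ident).startswith("Macrophage")]
        cell_clusters = assignment.labels
        meta = metadata.set_index("barcode").loc[expr.barcodes]
        is_macro_cell = np.isin(cell_clusters, macro_clusters)
        young = is_macro_cell & (meta["age"].to_numpy() == "young")
        old = is_macro_cell & (meta["age"].to_numpy() == "old")
        s2n = gsea_mod.signal_to_noise(expr, young, old)
        ranked = gsea_mod.rank_genes(s2n)
        res = gsea_mod.gsea(ranked, sets, n_perm=gs_cfg["n_perm"],
                            weight=gs_cfg["weight"],
                            seed=config.seed + STAGE_SEED_OFFSETS["gsea"])
        out = res.table.copy()
        out["leading_edge"] = out["leading_edge"].map(lambda g: ",".join(g))
        _df_tsv(out, outdir / "gsea_results.tsv")
        planted = res.table[res.table["set"].isin(truth.enriched_sets)]
        report["stages"]["gsea"] = {
            "n_sets": len(res.table),
            "n_young_macro_cells": int(young.sum()),
            "n_old_macro_cells": int(old.sum()),
            "planted_set_nes": round(float(planted["nes"].iloc[0]), 6),
            "planted_set_padj": round(float(planted["padj"].iloc[0]), 6),
            "n_enriched_padj05": int((res.table["padj"] < 0.05).sum()),
        }

    # --- metabolomics ---------------------------------------------------------
    with stage("metabolomics"):
        mt_cfg = config["metabolomics"]
        table, metab_truth = simulate_metabolites(sim_cfg)
        io.write_metabolite_table(table, outdir / "metabolites.csv",
                                  outdir / "metabolite_groups.csv")
        processed = metab.process_metabolites(table, mt_cfg["glog_lambda"])
        processed.values.to_csv(outdir / "metabolites_processed.tsv", sep="\t",
                                float_format="%.10g")
        Z, _ = metab.hierarchical_cluster(processed)
        (outdir / "metabolite_dendrogram.nwk").write_text(
            metab.linkage_to_newick(Z, processed.values.index.tolist()) + "\n")
        vol = metab.volcano(table, fc_cut=mt_cfg["fc_cut"], p_cut=mt_cfg["p_cut"],
                            lam=mt_cfg["glog_lambda"])
        _df_tsv(vol, outdir / "volcano.tsv")
        flagged = set(vol.loc[vol["significant"], "metabolite"])
        planted_names = {m for m, fc in metab_truth.metab_log2fc.items() if fc != 0}
        report["stages"]["metabolomics"] = {
            "n_metabolites": len(table.metabolites),
            "n_flagged": len(flagged),
            "planted_recovered": len(flagged & planted_names),
            "n_planted": len(planted_names),
        }

    # --- bioenergetics ---------------------------------------------------------
    with stage("bioenergetics"):
        bio_cfg = config["bioenergetics"]
        trace = simulate_ecar_trace(sim_cfg)
        io.write_ecar_trace(trace, outdir / "ecar_trace.csv", outdir / "protein.csv")
        per_well = be.per_well_metrics(trace, aggregation=bio_cfg["aggregation"],
                                       normalize=bio_cfg["normalize_protein"])
        per_well["group"] = per_well["well"].str.rsplit("_", n=1).str[0]
        _df_tsv(per_well, outdir / "glycolysis_metrics.tsv")
        beads = simulate_bead_counts(sim_cfg)
        beads.to_csv(outdir / "bead_counts.csv", index=False)
        phago = be.phagocytosis_index(beads)
        _df_tsv(phago.well_means, outdir / "phagocytosis_wells.tsv")
        group_means = per_well.groupby("group")[
            ["glycolysis", "glycolytic_capacity", "glycolytic_reserve"]].mean()
        report["stages"]["bioenergetics"] = {
            "n_wells": len(per_well),
            "glycolysis_by_group": {g: round(float(v), 6)
                                    for g, v in group_means["glycolysis"].items()},
            "phagocytosis_by_group": {g: round(float(v), 6)
                                      for g, v in phago.group_means.items()},
        }

    for name, dt in timings.items():
        logger.info("timing %s: %.3fs", name, dt)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
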