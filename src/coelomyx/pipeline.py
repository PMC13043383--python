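"""Configuration-driven orchestration of the synthetic-to-results pipeline.

A single YAML config (all parameters defaulting to the analysis' standard
thresholds) drives simulate -> qc -> celltype -> DE -> co-expression ->
enrichment (-> assays), with one global seed expanded deterministically into
per-stage substreams. Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assays, celltyping, coexpr, diffexpr, qc, simdata, stats_enrich

log = logging.getLogger("coelomyx")
if not log.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "qc": True,
        "celltype": True,
        "sc_de": True,
        "coexpr": True,
        "enrich": True,
        "bulk": True,
        "assays": False,
    },
    "simdata": {
        "n_cells_per_sample": 1000,
        "n_samples_per_condition": 3,
        "proportions": dict(simdata.DEFAULT_PROPORTIONS),
        "depth_mean": 5000.0,
        "depth_cv": 0.5,
        "n_genes": 200,
        "marker_fold": 8.0,
        "n_de_genes": 20,
        "de_log2fc": 2.0,
        "n_dc_pairs": 5,
        "dc_rho_control": 0.0,
        "dc_rho_treated": 0.6,
    },
    "qc": {"n_mads": 5.0, "min_cells_per_gene": 50},
    "celltyping": {"alpha": 0.05, "min_log2fc": 0.5},
    "sc_de": {"alpha": 0.05, "min_abs_log2fc": 1.0, "min_cells": 20},
    "coexpr": {
        "n_per_group": 10000,
        "n_permutations": 1000,
        "q_threshold": 0.05,
        "rho_threshold": 0.5,
    },
    "bulk": {
        "n_genes": 2000,
        "n_replicates": 3,
        "dispersion": 0.05,
        "de_fraction": 0.1,
        "de_log2fc": 2.0,
        "pover_a_count": 10,
        "pover_a_samples": 3,
        "alpha": 0.05,
        "min_abs_log2fc": 1.0,
    },
}

SMALL_PRESET = {
    "simdata": {"n_cells_per_sample": 333},
    "coexpr": {"n_per_group": 1000, "n_permutations": 100},
    "bulk": {"n_genes": 500},
}


class ConfigError(ValueError):
    """Raised with the exhaustive list of config schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.values[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()
        ).hexdigest()[:16]


_POSITIVE = {
    ("qc", "n_mads"),
    ("simdata", "n_cells_per_sample"),
    ("simdata", "depth_mean"),
    ("simdata", "marker_fold"),
    ("celltyping", "alpha"),
    ("celltyping", "min_log2fc"),
    ("sc_de", "alpha"),
    ("coexpr", "n_per_group"),
    ("coexpr", "n_permutations"),
    ("bulk", "n_genes"),
    ("bulk", "pover_a_count"),
    ("bulk", "pover_a_samples"),
}


def validate_config(source=None) -> PipelineConfig:
    """Normalize a config mapping / YAML path against the schema.

    Unknown keys are rejected; all violations are reported together. An empty
    or missing source yields the full default configuration.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    if raw.get("preset") == "small":
        raw.pop("preset")
        merged_raw = copy.deepcopy(SMALL_PRESET)
        for k, v in raw.items():
            if isinstance(v, dict) and isinstance(merged_raw.get(k), dict):
                merged_raw[k].update(v)
            else:
                merged_raw[k] = v
        raw = merged_raw

    errors: list[str] = []
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in raw.items():
        if key not in merged:
            errors.append(f"unknown key: {key}")
            continue
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{key} must be a mapping")
                continue
            for sub, sval in val.items():
                if sub not in merged[key]:
                    errors.append(f"unknown key: {key}.{sub}")
                else:
                    merged[key][sub] = sval
        else:
            merged[key] = val

    for section, name in _POSITIVE:
        try:
            if merged[section][name] <= 0:
                errors.append(f"{section}.{name} must be > 0")
        except TypeError:
            errors.append(f"{section}.{name} must be numeric")
    props = merged["simdata"]["proportions"]
    if abs(sum(props.values()) - 1.0) > 1e-8:
        errors.append("simdata.proportions must sum to 1")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(values=merged)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return int(np.random.SeedSequence([int(global_seed), stage_index]).generate_state(1)[0] % (2**31))


def _save(df: pd.DataFrame, outdir: str, name: str, manifest: dict, index=True) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=index)
    with open(path, "rb") as fh:
        manifest["outputs"][name] = hashlib.sha256(fh.read()).hexdigest()


def run_pipeline(config: PipelineConfig | dict | None, outdir: str) -> dict:
    """Execute the configured stages, writing TSV results and a manifest.

    Stage failures abort with the stage name in the raised error; outputs of
    completed stages remain on disk. Returns the manifest (also written as
    ``manifest.json``).
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    cfg = config.values
    seed = int(cfg["seed"])
    manifest: dict = {
        "config_hash": config.hash(),
        "config": cfg,
        "stages_run": [],
        "stage_seeds": {},
        "outputs": {},
    }
    stage_names = ["simulate", "qc", "celltype", "sc_de", "coexpr", "enrich", "bulk", "assays"]
    seeds = {name: stage_seed(seed, i) for i, name in enumerate(stage_names)}
    manifest["stage_seeds"] = seeds
    state: dict = {}

    def run_stage(name, fn):
        if not cfg["stages"].get(name, False):
            return
        log.info("stage %s (seed %d)", name, seeds[name])
        try:
            fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages_run"].append(name)

    def do_simulate():
        sd = cfg["simdata"]
        model = simdata.default_latent_model(
            n_genes=sd["n_genes"],
            seed=seeds["simulate"],
            marker_fold=sd["marker_fold"],
            n_de_genes=sd["n_de_genes"],
            de_log2fc=sd["de_log2fc"],
            n_dc_pairs=sd["n_dc_pairs"],
            dc_rho_control=sd["dc_rho_control"],
            dc_rho_treated=sd["dc_rho_treated"],
        )
        design = simdata.CohortDesign(
            n_cells_per_sample=sd["n_cells_per_sample"],
            n_samples_per_condition=sd["n_samples_per_condition"],
            proportions=sd["proportions"],
            depth_mean=sd["depth_mean"],
            depth_cv=sd["depth_cv"],
            seed=seeds["simulate"],
        )
        adata, cells, truth = simdata.simulate_single_cell_cohort(design, model)
        state.update(adata=adata, truth=truth)
        _save(cells, outdir, "cells.tsv", manifest, index=False)

    def do_qc():
        params = qc.QCParams(
            n_mads=cfg["qc"]["n_mads"], min_cells_per_gene=cfg["qc"]["min_cells_per_gene"]
        )
        filtered, report = qc.filter_cells_mad(state["adata"], params)
        filtered = qc.filter_genes_min_cells(filtered, params)
        state["adata_norm"] = qc.normalize_log(filtered)
        _save(report, outdir, "qc_removed_cells.tsv", manifest, index=False)

    def do_celltype():
        ct_cfg = cfg["celltyping"]
        params = celltyping.MarkerCallParams(alpha=ct_cfg["alpha"], min_log2fc=ct_cfg["min_log2fc"])
        markers = celltyping.rank_cluster_markers(state["adata_norm"], "cluster", params)
        assignment = celltyping.assign_cell_types(markers)
        adn = state["adata_norm"]
        adn.obs["cell_type"] = adn.obs["cluster"].astype(str).map(assignment)
        fractions = celltyping.cell_type_fractions(adn.obs)
        cond = adn.obs.groupby("sample", observed=True)["condition"].first()
        tests = celltyping.compare_fractions(fractions, cond)
        state.update(markers=markers, assignment=assignment, fractions=fractions)
        _save(markers, outdir, "cluster_markers.tsv", manifest, index=False)
        _save(pd.Series(assignment, name="cell_type").rename_axis("cluster").to_frame(),
              outdir, "cluster_assignments.tsv", manifest)
        _save(fractions, outdir, "cell_type_fractions.tsv", manifest)
        _save(tests, outdir, "fraction_tests.tsv", manifest, index=False)

    def do_sc_de():
        de_cfg = cfg["sc_de"]
        table = diffexpr.sc_condition_de(
            state["adata_norm"],
            groupby="cell_type",
            alpha=de_cfg["alpha"],
            min_abs_log2fc=de_cfg["min_abs_log2fc"],
            min_cells=de_cfg["min_cells"],
        )
        state["sc_de"] = table
        _save(table, outdir, "sc_condition_de.tsv", manifest, index=False)

    def do_coexpr():
        cx = cfg["coexpr"]
        adn = state["adata_norm"]
        counts = adn.layers["counts"]
        phag = np.asarray(adn.obs["cell_type"] == "phagocyte")
        ctrl = phag & np.asarray(adn.obs["condition"] == "control")
        trt = phag & np.asarray(adn.obs["condition"] == "uvb")
        pairs = [(p["gene_j"], p["gene_k"]) for p in state["truth"]["dc_pairs"]]
        genes = list(adn.var_names)
        pairs = [p for p in pairs if p[0] in genes and p[1] in genes]
        # a few null background pairs alongside the planted ones
        bg = [g for g in genes if g.startswith("Bg")][:10]
        pairs += [(bg[i], bg[i + 1]) for i in range(0, len(bg) - 1, 2)]
        depths = np.asarray(counts.sum(axis=1)).ravel()
        records = {}
        for label, mask in (("control", ctrl), ("uvb", trt)):
            records[label] = coexpr.estimate_coexpression(
                counts[mask], depths[mask], pairs, gene_names=genes
            )
            _save(records[label], outdir, f"coexpression_{label}.tsv", manifest, index=False)
            retained = coexpr.filter_significant_pairs(
                records[label], cx["q_threshold"], cx["rho_threshold"]
            )
            _save(retained, outdir, f"coexpression_{label}_retained.tsv", manifest, index=False)
        dc = coexpr.differential_coexpression(
            counts[ctrl],
            counts[trt],
            pairs,
            gene_names=genes,
            depths_ctrl=depths[ctrl],
            depths_trt=depths[trt],
            n_per_group=cx["n_per_group"],
            n_permutations=cx["n_permutations"],
            seed=seeds["coexpr"],
        )
        state["diffcoexpr"] = dc
        _save(dc, outdir, "differential_coexpression.tsv", manifest, index=False)

    def do_enrich():
        truth = state["truth"]
        genes = list(state["adata_norm"].var_names)
        collection = stats_enrich.GeneSetCollection(
            sets={
                "planted_DE": set(truth["de_genes"]),
                **{f"markers_{t}": set(g) for t, g in truth["markers"].items()},
            },
            universe=set(genes),
        )
        de = state.get("sc_de")
        query = set(de.loc[(de["group"] == "phagocyte") & (de["call"] == 1), "gene"]) & set(genes)
        table = stats_enrich.hypergeometric_ora(query, collection)
        _save(table, outdir, "enrichment.tsv", manifest, index=False)

    def do_bulk():
        b = cfg["bulk"]
        design = simdata.BulkDesign(
            n_genes=b["n_genes"],
            n_replicates=b["n_replicates"],
            dispersion=b["dispersion"],
            de_fraction=b["de_fraction"],
            de_log2fc=b["de_log2fc"],
            seed=seeds["bulk"],
        )
        counts, truth = simdata.simulate_bulk_experiment(design)
        params = diffexpr.BulkDEParams(
            pover_a_count=b["pover_a_count"],
            pover_a_samples=b["pover_a_samples"],
            alpha=b["alpha"],
            min_abs_log2fc=b["min_abs_log2fc"],
        )
        filtered = diffexpr.pover_a_filter(counts, params)
        sf = diffexpr.median_of_ratios_size_factors(filtered)
        de_union: set = set()
        for tp in design.timepoints:
            cols_t = [c for c in filtered.columns if c.startswith(f"uvb_T{tp}_")]
            cols_c = [c for c in filtered.columns if c.startswith(f"control_T{tp}_")]
            res = diffexpr.nb_wald_test(filtered, sf, (cols_t, cols_c), params)
            de_union |= set(res.index[res["call"] != 0])
            _save(res, outdir, f"bulk_de_T{tp}.tsv", manifest)
        vst = diffexpr.vst_like_transform(filtered, sf)
        de_genes = sorted(de_union)
        if len(de_genes) >= 2:
            cond = pd.Series(
                ["uvb" if c.startswith("uvb") else "control" for c in vst.columns],
                index=vst.columns,
            )
            clusters = diffexpr.kmeans_gene_clusters(
                vst.loc[de_genes], cond, seed=seeds["bulk"]
            )
            _save(
                pd.DataFrame(
                    {"cluster": clusters.labels, "centroid_rho": clusters.centroid_corr}
                ),
                outdir,
                "bulk_gene_clusters.tsv",
                manifest,
            )
            rows = []
            for cl, members in clusters.labels.groupby(clusters.labels):
                sub = vst.loc[members.index]
                for col in sub.columns:
                    cond_name, tp, rep = col.split("_")
                    rows.append(
                        {
                            "cluster": cl,
                            "treatment": cond_name,
                            "time": tp,
                            "replicate": rep,
                            "value": float(sub[col].mean()),
                        }
                    )
            long = pd.DataFrame(rows)
            for cl, sub in long.groupby("cluster"):
                anova = diffexpr.cluster_mean_anova(sub)
                _save(anova, outdir, f"bulk_cluster{cl}_anova.tsv", manifest)
        state["bulk_truth"] = truth

    def do_assays():
        s = seeds["assays"]
        dr = simdata.simulate_assay_fixtures("dose_response", {"noise_cv": 0.05}, seed=s)
        fit = assays.fit_ld50_3param(dr["table"])
        comet = simdata.simulate_assay_fixtures("comet_masks", seed=s)
        rec = assays.comet_tail_percent(comet["image"], comet["head_mask"], comet["tail_mask"])
        pf = simdata.simulate_assay_fixtures("puncta_image", seed=s)
        puncta = assays.puncta_density_normalized(pf["signal"], pf["nuclei"])
        dens = assays.densitometry_normalize(
            {"L1": 1000.0, "L2": 800.0}, 100.0, {"L1": 450.0, "L2": 420.0}, 50.0
        )
        summary = pd.DataFrame(
            [
                {"assay": "ld50", "value": fit.ld50, "truth": dr["truth"]["ld50"]},
                {"assay": "tail_percent", "value": rec.tail_percent,
                 "truth": comet["truth"]["tail_percent"]},
                {"assay": "puncta_density", "value": puncta["density_per_nucleus"],
                 "truth": pf["truth"]["density_per_nucleus"]},
            ]
        )
        _save(summary, outdir, "assay_summary.tsv", manifest, index=False)
        _save(dens, outdir, "densitometry.tsv", manifest, index=False)

    run_stage("simulate", do_simulate)
    run_stage("qc", do_qc)
    run_stage("celltype", do_celltype)
    run_stage("sc_de", do_sc_de)
    run_stage("coexpr", do_coexpr)
    run_stage("enrich", do_enrich)
    run_stage("bulk", do_bulk)
    run_stage("assays", do_assays)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
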