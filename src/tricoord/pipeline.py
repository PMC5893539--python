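"""End-to-end orchestration: counts -> RPKM -> filter -> regression panel ->
indices -> permutation -> standardization -> dispersion -> UTR -> strata,
with a single reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config hash, the seed, per-stage gene counts and the headline
statistics, so re-running with the same config reproduces every output
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, indices, regression_stats, similarity_strata, synthetic_data, utr_analysis

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "profile": None,            # RPKM matrix TSV (skips the counts path)
    "counts": None,             # {assay: {replicate: path}}
    "lengths": None,            # gene-length TSV
    "annotation": None,         # GTF or UTR-length TSV
    "pairs": None,              # pair-score TSV
    "gene_sets": None,          # {name: [gene ids]} or {name: path}
    "synth": None,              # SyntheticTruth overrides (dict) to generate input
    "cutoff": 1.0,
    "min_params": 1,
    "pooling": "mean",
    "n_reps": 1000,
    "seed": 0,
    "shared_permutation": False,
    "pseudocount": 0.0,
    "correlation_method": "pearson",
    "ci_tail": 0.0125,
    "stability_min": 0.0,
    "translation_max": -1.0,
    "utr_bin_width": 0.1,
    "min_occupancy": 50,
    "score_bins": [0.25, 0.5, 0.75, 1.0],
    "max_background_pairs": 200000,
    "out_dir": "tricoord_out",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        config.update(loaded)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: dict):
    """Resolve the input profile plus optional annotation/pair tables."""
    utr = pairs = None
    if config.get("synth"):
        synth_conf = dict(config["synth"])
        synth_conf.setdefault("seed", config["seed"])
        if "utr_beta_params" in synth_conf:
            synth_conf["utr_beta_params"] = tuple(synth_conf["utr_beta_params"])
        dataset = synthetic_data.generate(synthetic_data.SyntheticTruth(**synth_conf))
        profile, utr, pairs = dataset.profile, dataset.utr, dataset.pairs
    elif config.get("profile"):
        profile = data_io.read_profile(config["profile"])
    elif config.get("counts"):
        if not config.get("lengths"):
            raise ValueError("the counts path requires a gene-length table")
        lengths = data_io.read_lengths(config["lengths"])
        tables = []
        for assay, reps in config["counts"].items():
            for rep, path in reps.items():
                tables.append(data_io.read_counts(path, assay=assay, replicate=int(rep)))
        profile = data_io.profile_from_counts(tables, lengths, pooling=config["pooling"])
    else:
        raise ValueError("config must supply one of: synth, profile, counts")

    if config.get("annotation"):
        utr = utr_analysis.annotate_utr(config["annotation"])
    if config.get("pairs"):
        pairs = similarity_strata.read_pair_scores(config["pairs"])
    return profile, utr, pairs


def _load_gene_sets(spec) -> dict[str, list[str]]:
    sets = {}
    for name, value in (spec or {}).items():
        if isinstance(value, (list, tuple)):
            sets[name] = list(value)
        else:
            sets[name] = [ln.strip() for ln in Path(value).read_text().splitlines() if ln.strip()]
    return sets


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every enabled stage, write its outputs, and return the manifest."""
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "seed": config["seed"],
                      "stages": {}, "headline": {}, "skipped": []}

    profile, utr, pairs = _load_inputs(config)
    filtered, report = data_io.filter_expressed(profile, cutoff=config["cutoff"],
                                                min_params=config["min_params"])
    data_io.write_profile(filtered, out / "profile.tsv")
    data_io.write_filter_report(report, out / "filter_report.json")
    manifest["stages"]["filter"] = report

    if filtered.replicates is not None:
        cons = data_io.replicate_consistency(filtered)
        cons.to_csv(out / "replicate_consistency.tsv", sep="\t", index=False)
        manifest["headline"]["replicate_r2_min"] = float(cons["r_squared"].min())
    else:
        manifest["skipped"].append("replicate_consistency: no replicates")

    panel = regression_stats.pairwise_panel(filtered)
    fits_json = {k: regression_stats.fit_to_dict(f) for k, f in panel.items()}
    comparisons = {}
    if "ra2_vs_ra1" in panel:
        for key in ("tr_vs_ra", "ta_vs_ra"):
            cmp_ = regression_stats.compare_slopes(panel[key], panel["ra2_vs_ra1"],
                                                   tail=config["ci_tail"])
            comparisons[f"{key}_vs_noise"] = regression_stats.comparison_to_dict(cmp_)
    (out / "fits.json").write_text(json.dumps({"fits": fits_json,
                                               "comparisons": comparisons}, indent=2,
                                              default=_json_default))
    manifest["headline"]["slopes"] = {k: f.slope for k, f in panel.items()}
    if comparisons:
        manifest["headline"]["ta_vs_noise_t_score"] = comparisons["ta_vs_ra_vs_noise"]["t_score"]
        manifest["headline"]["ta_vs_noise_log10_p"] = comparisons["ta_vs_ra_vs_noise"]["log10_p"]

    table = indices.compute_indices(filtered, pseudocount=config["pseudocount"])
    table.to_csv(out / "indices.tsv", sep="\t")
    assoc = indices.index_association(table, method=config["correlation_method"])
    manifest["stages"]["indices"] = {"n_genes": int(len(table))}
    manifest["headline"]["index_correlation"] = assoc.r
    manifest["headline"]["index_slope"] = assoc.slope

    perm = indices.permutation_null(filtered, n_reps=config["n_reps"],
                                    seed=config["seed"],
                                    shared_permutation=config["shared_permutation"])
    pd.DataFrame({"rep": np.arange(1, perm.n_reps + 1),
                  "correlation": perm.correlations,
                  "slope": perm.slopes}).to_csv(out / "permutation.tsv", sep="\t", index=False)
    (out / "permutation_summary.json").write_text(json.dumps(perm.summary(), indent=2, default=_json_default))
    manifest["headline"]["permutation_max_correlation"] = float(perm.correlations.max())

    standardized = indices.standardize_profiles(filtered)
    assoc_std = indices.index_association(indices.compute_indices(standardized),
                                          method=config["correlation_method"])
    manifest["headline"]["index_correlation_standardized"] = assoc_std.r

    disp = indices.dispersion_summary(filtered)
    disp.to_csv(out / "dispersion.tsv", sep="\t", index=False)
    manifest["headline"]["dispersion_sd"] = dict(zip(disp["parameter"], disp["sd"]))

    if utr is not None:
        edges = np.arange(0.0, 1.0 + config["utr_bin_width"], config["utr_bin_width"])
        curve = utr_analysis.utr_binned_association(table, utr, bin_edges=edges,
                                                    min_occupancy=config["min_occupancy"])
        curve.to_csv(out / "utr_curve.tsv", sep="\t", index=False)
        argmax = curve.loc[curve["pearson_r"].idxmax()]
        manifest["headline"]["utr_argmax_bin_center"] = float(argmax["bin_center"])

        sel = utr_analysis.select_defiers(table, stability_min=config["stability_min"],
                                          translation_max=config["translation_max"])
        pd.Series(list(sel.gene_ids), name="gene_id").to_csv(out / "defiers.tsv",
                                                             sep="\t", index=False)
        manifest["stages"]["defiers"] = {"n_selected": sel.n}
        if sel.n >= 3:
            shift = utr_analysis.utr_shift_test(sel, utr)
            manifest["headline"]["defier_utr_shift_p"] = shift.p_value
            manifest["headline"]["defier_utr_mean"] = shift.selection_mean
            manifest["headline"]["background_utr_mean"] = shift.background_mean
        gene_sets = _load_gene_sets(config.get("gene_sets"))
        if len(gene_sets) >= 2:
            summary = utr_analysis.group_utr_summary(gene_sets, utr)
            (out / "group_utr_summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
            manifest["stages"]["group_utr"] = {k: v["n"] for k, v in summary["groups"].items()}
    else:
        manifest["skipped"].append("utr: no annotation supplied")

    if pairs is not None and len(pairs):
        strata = similarity_strata.stratify(table, pairs, config["score_bins"],
                                            max_background_pairs=config["max_background_pairs"],
                                            seed=config["seed"])
        tests = similarity_strata.stratum_shift_test(strata)
        tests.to_csv(out / "strata_summary.tsv", sep="\t", index=False)
        similarity_strata.strata_histograms(strata).to_csv(out / "strata_histograms.tsv",
                                                           sep="\t", index=False)
        manifest["headline"]["strata_medians"] = dict(zip(tests["stratum"], tests["median"]))
    else:
        manifest["skipped"].append("strata: no pair scores supplied")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest
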