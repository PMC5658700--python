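"""End-to-end orchestration: annotate -> classify -> dynamics ->
expression / features / enrichment, with a manifest of everything read,
written and counted.

The pipeline is driven by a plain dict (or YAML file) with either
``simulate: true`` (inputs generated in memory by
:mod:`promoterpoise.simulate`) or an ``inputs`` section mapping every
required file, including one enriched-region BED per (mark, time
point); a missing combination aborts before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import dynamics as dyn
from . import enrichment as enr
from . import expression as expr
from . import features as feat
from . import simulate as sim
from .intervals import GenomicInterval, by_chrom
from .state_classification import MARKS, TIMEPOINTS, classify_promoters

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return df[["chrom", "start", "end"]]


def _load_inputs(config: dict, timepoints: tuple[str, ...]) -> dict:
    if config.get("simulate", False):
        sim_cfg = sim.SimulationConfig(
            **{**config.get("simulate_config", {}), "seed": int(config.get("seed", 0))}
        )
        return sim.generate_all(sim_cfg)
    inputs = config.get("inputs")
    if not inputs:
        raise ValueError("config needs either simulate: true or an inputs section")
    regions_cfg = inputs.get("regions", {})
    missing = [
        (mark, tp)
        for mark in MARKS
        for tp in timepoints
        if not regions_cfg.get(mark, {}).get(tp)
    ]
    if missing:
        raise ValueError(f"missing enriched-region files for: {missing}")
    bundle = {
        "isoforms": pd.read_csv(inputs["isoforms"], sep="\t"),
        "isoform_counts": pd.read_csv(inputs["isoform_counts"], sep="\t"),
        "gene_counts": pd.read_csv(inputs["gene_counts"], sep="\t"),
        "regions": {
            (mark, tp): _read_bed3(regions_cfg[mark][tp])
            for mark in MARKS
            for tp in timepoints
        },
        "tpm": pd.read_csv(inputs["tpm"], sep="\t", index_col="gene"),
        "ko": pd.read_csv(inputs["knockout"], sep="\t"),
        "cgi": _read_bed3(inputs["cgi"]),
        "hmr": _read_bed3(inputs["hmr"]),
        "ranks": pd.read_csv(inputs["ranks"], sep="\t"),
        "truth": None,
        "config": None,
    }
    return bundle


def run_pipeline(config: dict | str | Path, outdir=None) -> dict:
    """Run every stage on simulated or file inputs; write outputs and a
    JSON manifest; return the manifest (with the result tables attached
    under ``tables``)."""
    if not isinstance(config, dict):
        config = load_config(config)
    timepoints = tuple(config.get("timepoints", TIMEPOINTS))
    outdir = Path(outdir or config.get("outdir", "promoterpoise_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    bundle = _load_inputs(config, timepoints)
    manifest: dict = {
        "config_hash": _config_hash({k: v for k, v in config.items() if k != "outdir"}),
        "seed": seed,
        "stages": {},
        "outputs": {},
    }
    tables: dict = {}

    # ---- annotate ----
    clusters = ann.filter_clusters(bundle["isoforms"])
    gene_table = ann.build_gene_table(
        clusters, bundle["isoform_counts"], timepoints, seed=seed
    )
    tables["gene_table"] = gene_table
    manifest["stages"]["annotate"] = {
        "n_clusters": len(clusters),
        "n_rows": len(gene_table),
    }

    # ---- classify ----
    cls_cfg = config.get("classification", {})
    res = classify_promoters(
        gene_table,
        bundle["regions"],
        bundle["gene_counts"],
        timepoints,
        quantile=cls_cfg.get("quantile", 0.05),
        inclusive=cls_cfg.get("inclusive", False),
        max_window_overlap=cls_cfg.get("max_window_overlap", 200),
        overlap_policy=cls_cfg.get("overlap_policy", "both"),
    )
    states_all = res["states"]
    analysis_set = res["analysis_set"]
    states = states_all[states_all["gene"].isin(analysis_set)]
    tables["states"] = states_all
    tables["thresholds"] = res["thresholds"]
    per_state = {
        tp: states[states["timepoint"] == tp]["state"].value_counts().to_dict()
        for tp in timepoints
    }
    manifest["stages"]["classify"] = {
        "n_classified": len(analysis_set),
        "n_na_excluded": states_all["gene"].nunique() - len(analysis_set),
        "per_state_counts": per_state,
    }
    for tp in timepoints:
        if sum(per_state[tp].values()) != len(analysis_set):
            raise AssertionError("state counts do not sum to the analysis-set size")

    # ---- dynamics ----
    dynamics_table = dyn.prc_dynamics_table(states, timepoints)
    acquisition = dyn.transient_acquisition(states, timepoints)
    fates = dyn.prcs5p_fates(states, timepoints)
    tables["dynamics"] = dynamics_table
    tables["acquisition"] = acquisition
    tables["fates"] = fates
    manifest["stages"]["dynamics"] = {
        "groups": dynamics_table["dynamics_group"].value_counts().to_dict(),
        "n_always_prcs5p": int(fates["always_prcs5p"].sum()) if len(fates) else 0,
    }

    # ---- expression ----
    tpm = bundle["tpm"].loc[bundle["tpm"].index.intersection(analysis_set)]
    peaking = expr.select_peaking_genes(tpm[list(timepoints)])
    first_tp = timepoints[0]
    st0 = states[states["timepoint"] == first_tp].set_index("gene")["state"]
    ko = bundle["ko"].set_index("gene")
    up = pd.Series(
        expr.call_upregulated(ko["wt_expr"], ko["ko_expr"]), index=ko.index
    )
    ko_fracs = expr.per_state_upregulation(st0, up, ko["wt_expr"])
    tables["peaking"] = peaking
    tables["ko_fractions"] = ko_fracs
    manifest["stages"]["expression"] = {
        "n_peaking": len(peaking),
        "ko_fractions": {
            r.state: r.fraction for r in ko_fracs.itertuples() if r.defined
        },
    }

    # ---- features ----
    feat_cfg = config.get("dmv", {})
    merged = feat.cluster_hmrs(bundle["hmr"], max_gap=feat_cfg.get("max_gap", 1000))
    dmvs = feat.define_dmvs(merged, min_length=feat_cfg.get("min_length", 5000))
    last_tp = timepoints[-1]
    gt_last = gene_table[gene_table["timepoint"] == last_tp]
    cgi_by_chrom = by_chrom(bundle["cgi"])
    k27_regions = by_chrom(bundle["regions"][("H3K27me3", last_tp)])
    feat_rows = []
    for r in gt_last.itertuples():
        if r.cluster_id not in set(analysis_set):
            continue
        win = GenomicInterval(r.chrom, r.tss_win_start, r.tss_win_end)
        cgs, cge = cgi_by_chrom.get(r.chrom, (pd.array([]), pd.array([])))
        ks, ke = k27_regions.get(r.chrom, (pd.array([]), pd.array([])))
        feat_rows.append(
            {
                "gene": r.cluster_id,
                "k27_breadth": feat.h3k27me3_breadth(win, ks, ke),
                "cgi_tss": feat.cgi_coverage(win, cgs, cge),
                "methylation_class": feat.promoter_methylation_class(
                    win, dmvs, bundle["hmr"]
                ),
            }
        )
    features = pd.DataFrame(feat_rows)
    tables["features"] = features
    tables["dmvs"] = dmvs
    manifest["stages"]["features"] = {
        "n_dmvs": len(dmvs),
        "methylation_classes": features["methylation_class"].value_counts().to_dict()
        if len(features)
        else {},
    }

    # ---- enrichment ----
    ranks = bundle["ranks"]
    nn = ranks[ranks["conversion"].isin(sim.NON_NEURONAL_CONVERSIONS)]
    mean_rank = nn.groupby("tf")["rank"].mean().sort_values(kind="stable")
    max_rank = int(ranks["rank"].max())
    ranked = mean_rank.index.tolist()
    scores = (max_rank - mean_rank + 1).to_numpy()
    st_last = states[states["timepoint"] == last_tp].set_index("gene")["state"]
    tf_states = st_last.reindex(ranked).dropna()
    gene_sets = {
        f"day30_{s}": set(tf_states.index[tf_states == s])
        for s in tf_states.unique()
        if 0 < (tf_states == s).sum() < len(ranked)
    }
    always = set(dyn.always_state_genes(states, timepoints, "PRC_S5p")) & set(ranked)
    if 0 < len(always) < len(ranked):
        gene_sets["always_PRC_S5p"] = always
    if gene_sets:
        gsea = enr.gsea_preranked(
            ranked,
            scores,
            gene_sets,
            n_permutations=int(config.get("gsea_permutations", 1000)),
            seed=seed,
        )
    else:
        gsea = pd.DataFrame()
    tables["gsea"] = gsea
    tables["tf_ranks"] = ranks
    manifest["stages"]["enrichment"] = {
        "n_tfs_ranked": len(ranked),
        "gsea": {
            r.gene_set: {"es": r.es, "nes": r.nes, "fdr": r.fdr, "direction": r.direction}
            for r in gsea.itertuples()
        }
        if len(gsea)
        else {},
    }

    # ---- write ----
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            manifest["outputs"][name] = str(path)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    manifest["outputs"]["manifest"] = str(manifest_path)
    manifest["tables"] = tables
    if bundle.get("truth") is not None:
        manifest["tables"]["truth"] = bundle["truth"]
    return manifest
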