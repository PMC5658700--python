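"""Synthetic multi-omics cohort with planted ground truth.

The generator emulates the data shapes of a five-time-point neuronal
differentiation ChIP-seq / mRNA-seq study on a miniature genome (by
default two 10-Mb chromosomes, 1,000 genes) so that every pipeline
stage can be exercised offline and checked against a known answer:

* an isoform/cluster annotation table with canonical and RefSeq flags,
  chrM and ``*_random`` decoy clusters, and (optionally) deliberately
  window-overlapping or nested gene pairs to trigger the exclusion
  filters;
* per-mark, per-time-point enriched regions plus TSS-window read
  counts, driven by planted promoter-state trajectories (negative
  binomial counts for positive windows; enriched regions three-fold
  broader at always-poised genes); a configurable fraction of
  planted-negative promoters receives a decoy enriched region with a
  zero read count, which anchors the empirical 5%-tail threshold below
  every true positive;
* TPM expression matrices coupled to the planted states (productive
  S7p+ states draw from a high log-normal component) with planted
  single-time-point peaking genes, and wild-type/knockout expression
  tables with per-state planted derepression probabilities;
* CpG-island and hypomethylated-region tracks that place always-poised
  promoters inside DMV-scale hypomethylated clusters, and TF influence
  rank tables biased low (influential) for the planted poised TFs in
  non-neuronal conversions.

A single seed drives per-component child RNG streams (numpy
``SeedSequence.spawn``), so each component is individually reproducible
and every generated table is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .state_classification import TIMEPOINTS

__all__ = [
    "ARCHETYPES",
    "SimulationConfig",
    "generate_truth",
    "generate_annotation",
    "generate_mark_data",
    "generate_expression",
    "generate_tracks_and_ranks",
    "generate_all",
    "write_cohort",
]

# state -> (H3K27me3, S5p, S7p) positivity
STATE_MARKS = {
    "PRC_S5p": (True, True, False),
    "PRC_Active": (True, True, True),
    "PRC_Only": (True, False, False),
    "PRC_S7p": (True, False, True),
    "Active": (False, True, True),
    "Inactive": (False, False, False),
    "S5p_Only": (False, True, False),
    "S7p_Only": (False, False, True),
}

ARCHETYPES = (
    "always_prcs5p",
    "prcs5p_to_prconly",
    "prcs5p_to_inactive",
    "prcs5p_to_active",
    "prconly_always",
    "acquired_retained",
    "acquired_transient",
    "always_active",
    "always_inactive",
    "s5p_only_always",
    "prc_active_always",
)

DEFAULT_GROUP_FRACTIONS = {
    "always_prcs5p": 0.05,
    "prcs5p_to_prconly": 0.05,
    "prcs5p_to_inactive": 0.07,
    "prcs5p_to_active": 0.08,
    "prconly_always": 0.05,
    "acquired_retained": 0.08,
    "acquired_transient": 0.07,
    "always_active": 0.25,
    "always_inactive": 0.25,
    "s5p_only_always": 0.03,
    "prc_active_always": 0.02,
}

NON_NEURONAL_CONVERSIONS = ("cardiomyocyte", "fibroblast", "skeletal_muscle", "hepatocyte")
NEURONAL_CONVERSIONS = ("neuron", "hippocampus")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give well-separated count components (negative-binomial
    means 200 vs 2), DMV placement probabilities of 0.65 for
    always-poised promoters vs 0.02 for poised-to-inactive ones, and
    knockout derepression probabilities of 0.30 (PRC/S5p), 0.05
    (PRC Only) and 0.02 (Inactive).
    """

    n_genes: int = 1000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    timepoints: tuple[str, ...] = TIMEPOINTS
    group_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FRACTIONS)
    )
    # gene geometry (bp)
    min_gene_length: int = 2000
    max_gene_length: int = 10000
    min_gap: int = 8000
    max_gap: int = 16000
    max_isoforms: int = 4
    isoform_tss_jitter: int = 300
    tss_overlap_fraction: float = 0.0
    nested_fraction: float = 0.0
    # window counts (negative binomial mean/dispersion)
    positive_count_mean: float = 200.0
    positive_count_dispersion: float = 10.0
    negative_count_mean: float = 2.0
    negative_count_dispersion: float = 5.0
    decoy_region_prob: float = 0.3
    # enriched-region geometry
    region_width_mean: float = 3000.0
    region_width_sigma: float = 0.2
    region_width_min: int = 2200
    region_width_max: int = 3800
    broad_width_factor: float = 3.0
    # expression coupling
    expressed_tpm_log_mean: float = math.log(50.0)
    expressed_tpm_log_sigma: float = 1.0
    silent_tpm_log_mean: float = math.log(0.05)
    silent_tpm_log_sigma: float = 1.0
    peaking_fraction: float = 0.3
    peak_factor: float = 100.0
    # knockout derepression probabilities by first-time-point state
    ko_upregulation_probs: dict[str, float] = field(
        default_factory=lambda: {"PRC_S5p": 0.30, "PRC_Only": 0.05, "default": 0.02}
    )
    # methylation tracks
    p_dmv_always_poised: float = 0.65
    p_dmv_inactive_fate: float = 0.02
    p_dmv_other: float = 0.05
    p_hmr_only: float = 0.5
    # influence ranks
    max_rank: int = 303
    rank_bias_strength: float = 1.0
    tf_sample_per_group: int = 60
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.group_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"group fractions sum to {total} > 1")
        unknown = set(self.group_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown trajectory archetypes: {sorted(unknown)}")
        for k, v in self.group_fractions.items():
            if v < 0:
                raise ValueError(f"negative fraction for {k}")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    names = ["truth", "annotation", "marks", "expression", "tracks", "ranks"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# planted truth


def _states_for(archetype: str, rng: np.random.Generator, n_tp: int) -> tuple[str, ...]:
    if archetype == "always_prcs5p":
        return ("PRC_S5p",) * n_tp
    if archetype == "prconly_always":
        return ("PRC_Only",) * n_tp
    if archetype == "always_active":
        return ("Active",) * n_tp
    if archetype == "always_inactive":
        return ("Inactive",) * n_tp
    if archetype == "s5p_only_always":
        return ("S5p_Only",) * n_tp
    if archetype == "prc_active_always":
        return ("PRC_Active",) * n_tp
    if archetype in {"prcs5p_to_prconly", "prcs5p_to_inactive", "prcs5p_to_active"}:
        after = {
            "prcs5p_to_prconly": "PRC_Only",
            "prcs5p_to_inactive": "Inactive",
            "prcs5p_to_active": "Active",
        }[archetype]
        t = int(rng.integers(1, n_tp))
        return ("PRC_S5p",) * t + (after,) * (n_tp - t)
    if archetype == "acquired_retained":
        t = int(rng.integers(1, n_tp))
        return ("Inactive",) * t + ("PRC_Only",) * (n_tp - t)
    if archetype == "acquired_transient":
        t = int(rng.integers(1, n_tp - 1))
        t2 = int(rng.integers(t, n_tp - 1))
        return (
            ("Inactive",) * t
            + ("PRC_Only",) * (t2 - t + 1)
            + ("Inactive",) * (n_tp - t2 - 1)
        )
    raise ValueError(f"unknown archetype {archetype!r}")


def generate_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign archetypes, state trajectories and planted labels."""
    config.validate()
    n = config.n_genes
    n_tp = len(config.timepoints)
    counts = {a: int(round(config.group_fractions.get(a, 0.0) * n)) for a in ARCHETYPES}
    # absorb rounding drift into the inactive background
    counts["always_inactive"] += n - sum(counts.values())
    if counts["always_inactive"] < 0:
        raise ValueError("group fractions leave no room for the inactive background")

    rows = []
    i = 0
    for archetype in ARCHETYPES:
        for _ in range(counts[archetype]):
            states = _states_for(archetype, rng, n_tp)
            rows.append({"gene": f"g{i:04d}", "archetype": archetype, "states": states})
            i += 1
    truth = pd.DataFrame(rows)
    for j, tp in enumerate(config.timepoints):
        truth[f"state_{tp}"] = [s[j] for s in truth["states"]]

    flags = np.array(
        [[STATE_MARKS[s][0] for s in states] for states in truth["states"]]
    )
    truth["dynamics_group"] = np.select(
        [flags.all(axis=1), flags[:, 0], flags[:, 1:].any(axis=1)],
        ["Maintained", "Lost", "Acquired"],
        default="NeverPRC",
    )

    probs = config.ko_upregulation_probs
    p_up = truth[f"state_{config.timepoints[0]}"].map(
        lambda s: probs.get(s, probs.get("default", 0.0))
    )
    truth["ko_upregulated"] = rng.random(len(truth)) < p_up.to_numpy()

    p_dmv = np.select(
        [
            truth["archetype"] == "always_prcs5p",
            truth["archetype"] == "prcs5p_to_inactive",
        ],
        [config.p_dmv_always_poised, config.p_dmv_inactive_fate],
        default=config.p_dmv_other,
    )
    truth["dmv_member"] = rng.random(len(truth)) < p_dmv

    peaks = np.full(len(truth), "", dtype=object)
    active = np.flatnonzero((truth["archetype"] == "always_active").to_numpy())
    chosen = active[rng.random(active.size) < config.peaking_fraction]
    tp_idx = rng.integers(0, n_tp, size=chosen.size)
    for pos, j in zip(chosen, tp_idx):
        peaks[pos] = config.timepoints[j]
    truth["peak_timepoint"] = peaks

    is_tf = np.zeros(len(truth), dtype=bool)
    is_tf[(truth["archetype"] == "always_prcs5p").to_numpy()] = True
    for group in ("always_active", "always_inactive", "prconly_always"):
        idx = np.flatnonzero((truth["archetype"] == group).to_numpy())
        take = min(config.tf_sample_per_group, idx.size)
        is_tf[rng.choice(idx, size=take, replace=False)] = True
    truth["is_tf"] = is_tf
    return truth.drop(columns=["states"])


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place gene bodies and emit the isoform/cluster table.

    Returns ``(isoform_table, truth)`` where truth gains chrom/strand/
    tss columns (isoform 0 of each cluster, the one the selection
    cascade resolves to for positive promoters) and rows for any
    overlap/nested companion genes.
    """
    chroms = list(config.chrom_sizes)
    positions: dict[str, int] = {c: 5000 for c in chroms}
    rows = []
    truth = truth.copy().reset_index(drop=True)
    placed = []

    nested_candidates = set(
        rng.choice(
            len(truth),
            size=int(round(config.nested_fraction * len(truth))),
            replace=False,
        )
    )
    remaining = [i for i in range(len(truth)) if i not in nested_candidates]
    overlap_candidates = set(
        rng.choice(
            remaining,
            size=min(
                int(round(config.tss_overlap_fraction * len(truth))), len(remaining)
            ),
            replace=False,
        )
    )

    companions = []
    ci = 0
    for i, g in enumerate(truth.itertuples()):
        length = (
            int(rng.integers(9000, config.max_gene_length + 1))
            if i in nested_candidates
            else int(rng.integers(config.min_gene_length, config.max_gene_length + 1))
        )
        gap = int(rng.integers(config.min_gap, config.max_gap + 1))
        chrom = None
        for c in chroms:
            if positions[c] + length + gap < config.chrom_sizes[c] - 5000:
                chrom = c
                break
        if chrom is None:
            raise ValueError("infeasible packing: chromosomes too small for n_genes")
        start = positions[chrom]
        positions[chrom] = start + length + gap
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append(
            {"gene": g.gene, "chrom": chrom, "start": start, "end": start + length, "strand": strand}
        )
        rows.extend(_isoform_rows(g.gene, chrom, strand, start, start + length, config, rng))

        if i in nested_candidates:
            inner_s = start + length // 4
            inner_e = start + length - length // 4
            companions.append((g.gene, f"nest{ci:03d}", chrom, strand, inner_s, inner_e))
            ci += 1
        elif i in overlap_candidates:
            if strand == "+":
                ov_s, ov_e = start + 1000, start + 1000 + length
            else:
                ov_s, ov_e = start + length - 1000 - length, start + length - 1000
                ov_s = max(0, ov_s)
            companions.append((g.gene, f"ovlp{ci:03d}", chrom, strand, ov_s, ov_e))
            ci += 1

    comp_truth_rows = []
    for host, cid, chrom, strand, s, e in companions:
        rows.extend(_isoform_rows(cid, chrom, strand, s, e, config, rng, single=True))
        placed.append({"gene": cid, "chrom": chrom, "start": s, "end": e, "strand": strand})
        host_row = truth[truth["gene"] == host].iloc[0].to_dict()
        host_row.update({"gene": cid, "archetype": host_row["archetype"], "is_tf": False})
        comp_truth_rows.append(host_row)
    if comp_truth_rows:
        truth = pd.concat([truth, pd.DataFrame(comp_truth_rows)], ignore_index=True)

    geo = pd.DataFrame(placed).set_index("gene")
    truth["chrom"] = truth["gene"].map(geo["chrom"])
    truth["body_start"] = truth["gene"].map(geo["start"])
    truth["body_end"] = truth["gene"].map(geo["end"])
    truth["strand"] = truth["gene"].map(geo["strand"])
    truth["tss"] = np.where(
        truth["strand"] == "+", truth["body_start"], truth["body_end"]
    )

    # decoy clusters exercised by the annotation filters
    rows.extend(_isoform_rows("decoy_chrM", "chrM", "+", 100, 5100, config, rng, single=True))
    rows.extend(
        _isoform_rows("decoy_rand", "chr1_random", "+", 100, 5100, config, rng, single=True)
    )
    norefseq = _isoform_rows("decoy_noref", chroms[0], "+", 200, 5200, config, rng, single=True)
    for r in norefseq:
        r["refseq_flag"] = False
    rows.extend(norefseq)
    return pd.DataFrame(rows), truth


def _isoform_rows(cluster, chrom, strand, start, end, config, rng, single=False):
    n_iso = 1 if single else int(rng.integers(1, config.max_isoforms + 1))
    length = end - start
    rows = []
    coding = rng.permutation(n_iso)  # canonical = unique max coding bases
    for k in range(n_iso):
        jitter = 0 if k == 0 else int(rng.integers(1, config.isoform_tss_jitter + 1))
        if strand == "+":
            tx_s, tx_e = start + jitter, end
        else:
            tx_s, tx_e = start, end - jitter
        span = tx_e - tx_s
        cds_s = tx_s + span // 10
        cds_e = cds_s + max(300, span // 2 - int(coding[k]) * 50)
        cds_e = min(cds_e, tx_e)
        rows.append(
            {
                "isoform_id": f"{cluster}.{chr(ord('a') + k)}",
                "cluster_id": cluster,
                "chrom": chrom,
                "strand": strand,
                "txStart": tx_s,
                "txEnd": tx_e,
                "cdsStart": cds_s,
                "cdsEnd": cds_e,
                "refseq_flag": True,
                "canonical_flag": bool(coding[k] == 0),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# marks


def generate_mark_data(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Enriched regions and TSS-window read counts per (mark, time point).

    Returns dict with ``regions`` (mapping (mark, tp) -> BED-like
    frame), ``gene_counts`` (gene, mark, timepoint, count) and
    ``isoform_counts`` (isoform_id, timepoint, mark, count) for the
    isoform-selection cascade (isoform 0 carries the gene count; other
    isoforms carry 60% of it, so S5p resolves selection whenever the
    promoter has signal).
    """
    from .state_classification import MARKS

    regions: dict[tuple[str, str], pd.DataFrame] = {}
    count_rows = []
    iso_rows = []
    broad = (truth["archetype"] == "always_prcs5p").to_numpy()

    for tp_i, tp in enumerate(config.timepoints):
        states = truth[f"state_{tp}"].to_numpy()
        for m_i, mark in enumerate(MARKS):
            pos = np.array([STATE_MARKS[s][m_i] for s in states])
            n = len(truth)
            p_nb = config.positive_count_dispersion / (
                config.positive_count_dispersion + config.positive_count_mean
            )
            pos_counts = np.maximum(
                rng.negative_binomial(config.positive_count_dispersion, p_nb, size=n), 1
            )
            p_nb_lo = config.negative_count_dispersion / (
                config.negative_count_dispersion + config.negative_count_mean
            )
            neg_counts = rng.negative_binomial(
                config.negative_count_dispersion, p_nb_lo, size=n
            )
            decoy = (~pos) & (rng.random(n) < config.decoy_region_prob)

            counts = np.where(pos, pos_counts, np.where(decoy, 0, neg_counts))

            widths = np.exp(
                rng.normal(np.log(config.region_width_mean), config.region_width_sigma, size=n)
            )
            widths = np.clip(widths, config.region_width_min, config.region_width_max)
            if mark in ("H3K27me3", "S5p"):
                widths = np.where(broad, widths * config.broad_width_factor, widths)
            widths = widths.astype(int)

            has_region = pos | decoy
            tss = truth["tss"].to_numpy()
            reg = pd.DataFrame(
                {
                    "chrom": truth["chrom"].to_numpy()[has_region],
                    "start": np.maximum(tss[has_region] - widths[has_region] // 2, 0),
                    "end": tss[has_region] + widths[has_region] // 2,
                }
            ).sort_values(["chrom", "start"]).reset_index(drop=True)
            regions[(mark, tp)] = reg

            count_rows.append(
                pd.DataFrame(
                    {
                        "gene": truth["gene"],
                        "mark": mark,
                        "timepoint": tp,
                        "count": counts,
                    }
                )
            )
            if mark == "S5p":
                iso_rows.append(
                    pd.DataFrame(
                        {
                            "isoform_id": truth["gene"] + ".a",
                            "timepoint": tp,
                            "mark": "S5p",
                            "count": counts,
                        }
                    )
                )
                iso_rows.append(
                    pd.DataFrame(
                        {
                            "isoform_id": truth["gene"] + ".b",
                            "timepoint": tp,
                            "mark": "S5p",
                            "count": (counts * 0.6).astype(int),
                        }
                    )
                )
    gene_counts = pd.concat(count_rows, ignore_index=True)
    isoform_counts = pd.concat(iso_rows, ignore_index=True)
    return {"regions": regions, "gene_counts": gene_counts, "isoform_counts": isoform_counts}


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """TPM matrix coupled to planted states, plus WT/KO FPKM tables."""
    n = len(truth)
    tps = config.timepoints
    tpm = np.zeros((n, len(tps)))
    for j, tp in enumerate(tps):
        s7p = np.array([STATE_MARKS[s][2] for s in truth[f"state_{tp}"]])
        hi = rng.lognormal(config.expressed_tpm_log_mean, config.expressed_tpm_log_sigma, n)
        lo = rng.lognormal(config.silent_tpm_log_mean, config.silent_tpm_log_sigma, n)
        tpm[:, j] = np.where(s7p, hi, lo)

    # planted peaking genes: flat base, one inflated time point — the
    # one-spike pattern has z = 4/sqrt(5) ~ 1.789 > 1.75 at any scale
    peak = truth["peak_timepoint"].to_numpy()
    base = rng.lognormal(np.log(20.0), 0.3, n)
    for i in np.flatnonzero(peak != ""):
        j = list(tps).index(peak[i])
        tpm[i, :] = base[i]
        tpm[i, j] = base[i] * config.peak_factor

    tpm_df = pd.DataFrame(tpm, index=truth["gene"], columns=list(tps))
    tpm_df.index.name = "gene"

    first_state = truth[f"state_{tps[0]}"].to_numpy()
    repressed = np.isin(first_state, ["PRC_S5p", "PRC_Only", "Inactive"])
    wt = np.where(
        repressed,
        rng.lognormal(np.log(0.2), 0.7, n),
        rng.lognormal(np.log(30.0), 1.0, n),
    )
    up = truth["ko_upregulated"].to_numpy()
    ko_up = np.maximum(wt, 1e-3) * rng.uniform(3.0, 10.0, n)
    ko_up = np.maximum(ko_up, rng.uniform(1.5, 3.0, n))
    ko_flat = wt * rng.uniform(0.6, 1.4, n)
    ko = np.where(up, ko_up, ko_flat)
    ko_df = pd.DataFrame({"gene": truth["gene"], "wt_expr": wt, "ko_expr": ko})
    return {"tpm": tpm_df, "ko": ko_df}


# ---------------------------------------------------------------------------
# tracks & ranks


def generate_tracks_and_ranks(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """CGI and HMR BED tracks plus TF influence rank tables."""
    cgi_rows = []
    hmr_rows = []
    for g in truth.itertuples():
        tss = int(g.tss)
        if g.archetype == "always_prcs5p":
            cgi_rows.append({"chrom": g.chrom, "start": max(0, tss - 1500), "end": tss + 1500})
        elif g.archetype == "always_active":
            cgi_rows.append({"chrom": g.chrom, "start": max(0, tss - 250), "end": tss + 250})
        elif rng.random() < 0.3:
            cgi_rows.append({"chrom": g.chrom, "start": max(0, tss - 200), "end": tss + 200})

        if g.dmv_member:
            # three HMRs with 500-bp gaps: merges (gap <= 1 kb) into a
            # 6-kb hypomethylated block spanning the promoter
            for a, b in ((-3000, -1200), (-700, 700), (1200, 3000)):
                hmr_rows.append(
                    {"chrom": g.chrom, "start": max(0, tss + a), "end": tss + b}
                )
        elif rng.random() < config.p_hmr_only:
            hmr_rows.append({"chrom": g.chrom, "start": max(0, tss - 500), "end": tss + 500})

    cgi = pd.DataFrame(cgi_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    hmr = pd.DataFrame(hmr_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    tfs = truth[truth["is_tf"]]
    rank_rows = []
    bias = config.rank_bias_strength
    low_cap = max(2, int(config.max_rank * (1 - 0.8 * min(bias, 1.0))))
    for g in tfs.itertuples():
        poised = g.archetype == "always_prcs5p"
        active = g.archetype == "always_active"
        for conv in NON_NEURONAL_CONVERSIONS + NEURONAL_CONVERSIONS:
            non_neuronal = conv in NON_NEURONAL_CONVERSIONS
            if bias > 0 and ((poised and non_neuronal) or (active and not non_neuronal)):
                r = int(rng.integers(1, low_cap + 1))
            else:
                r = int(rng.integers(1, config.max_rank + 1))
            rank_rows.append({"tf": g.gene, "conversion": conv, "rank": r})
    ranks = pd.DataFrame(rank_rows, columns=["tf", "conversion", "rank"])
    return {"cgi": cgi, "hmr": hmr, "ranks": ranks}


# ---------------------------------------------------------------------------
# bundle


def generate_all(config: SimulationConfig | None = None, seed: int | None = None) -> dict:
    """Generate the full cohort: truth, annotation, marks, expression,
    tracks and ranks, as in-memory tables."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rngs = _streams(config)
    truth = generate_truth(config, rngs["truth"])
    isoforms, truth = generate_annotation(config, rngs["annotation"], truth)
    marks = generate_mark_data(truth, config, rngs["marks"])
    expr = generate_expression(truth, config, rngs["expression"])
    tracks = generate_tracks_and_ranks(truth, config, rngs["tracks"])
    return {
        "config": config,
        "truth": truth,
        "isoforms": isoforms,
        **marks,
        **expr,
        **tracks,
    }


def write_cohort(bundle: dict, outdir) -> dict[str, str]:
    """Write every table of a generated cohort as TSV/BED text files;
    returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        paths[name] = str(p)

    save(bundle["truth"], "truth.tsv")
    save(bundle["isoforms"], "isoforms.tsv")
    save(bundle["gene_counts"], "gene_counts.tsv")
    save(bundle["isoform_counts"], "isoform_counts.tsv")
    save(bundle["tpm"], "tpm.tsv", index=True)
    save(bundle["ko"], "knockout.tsv")
    save(bundle["cgi"], "cgi.bed")
    save(bundle["hmr"], "hmr.bed")
    save(bundle["ranks"], "ranks.tsv")
    for (mark, tp), reg in bundle["regions"].items():
        save(reg, f"regions_{mark}_{tp}.bed")
    return paths
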