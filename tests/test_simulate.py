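"""The synthetic cohort generator: determinism, planted structure,
round-tripping through the pipeline's readers."""

import numpy as np
import pandas as pd
import pytest

from conftest import TIMEPOINTS, truth_state_matrix
from promoterpoise.annotation import filter_clusters, read_isoform_table
from promoterpoise.simulate import (
    ARCHETYPES,
    STATE_MARKS,
    SimulationConfig,
    generate_all,
    write_cohort,
)
from promoterpoise.state_classification import positivity_threshold


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        a = write_cohort(generate_all(SimulationConfig(n_genes=60, seed=3)), tmp_path / "a")
        b = write_cohort(generate_all(SimulationConfig(n_genes=60, seed=3)), tmp_path / "b")
        assert set(a) == set(b)
        for name in a:
            assert open(a[name], "rb").read() == open(b[name], "rb").read()

    def test_different_seed_differs(self):
        a = generate_all(SimulationConfig(n_genes=60, seed=3))
        b = generate_all(SimulationConfig(n_genes=60, seed=4))
        assert not a["gene_counts"]["count"].equals(b["gene_counts"]["count"])


class TestPlantedTruth:
    def test_group_sizes_match_fractions(self, cohort):
        truth = cohort["truth"]
        base = truth[~truth["gene"].str.startswith(("nest", "ovlp"))]
        n = len(base)
        fr = cohort["config"].group_fractions
        for archetype in ARCHETYPES:
            expected = round(fr[archetype] * n)
            got = (base["archetype"] == archetype).sum()
            assert abs(got - expected) <= 2  # rounding drift absorbed elsewhere

    def test_trajectories_consistent_with_archetypes(self, cohort):
        truth = cohort["truth"]
        states = truth_state_matrix(truth)
        always = states[truth.set_index("gene")["archetype"] == "always_prcs5p"]
        assert (always == "PRC_S5p").to_numpy().all()
        # planted dynamics labels agree with the k27 flags of the states
        flags = states.map(lambda s: STATE_MARKS[s][0])
        m = flags.all(axis=1)
        labelled = truth.set_index("gene")["dynamics_group"]
        assert (labelled[m] == "Maintained").all()

    def test_planted_peaking_genes_are_recovered(self, cohort):
        from promoterpoise.expression import select_peaking_genes

        truth = cohort["truth"].set_index("gene")
        planted = truth[truth["peak_timepoint"] != ""]
        assert len(planted) > 0
        out = select_peaking_genes(cohort["tpm"]).set_index("gene")
        for gene, row in planted.iterrows():
            assert gene in out.index
            assert out.loc[gene, "peak_timepoint"] == row["peak_timepoint"]

    def test_ko_flags_recovered_exactly(self, cohort):
        from promoterpoise.expression import call_upregulated

        ko = cohort["ko"]
        got = call_upregulated(ko["wt_expr"], ko["ko_expr"])
        planted = cohort["truth"]["ko_upregulated"].to_numpy()
        assert (got == planted).all()


class TestAnnotationGeometry:
    def test_decoy_clusters_filtered_out_round_trip(self, cohort, tmp_path):
        iso = cohort["isoforms"]
        assert {"decoy_chrM", "decoy_rand", "decoy_noref"} <= set(iso["cluster_id"])
        path = tmp_path / "iso.tsv"
        iso.to_csv(path, sep="\t", index=False)
        clusters = filter_clusters(read_isoform_table(path))
        ids = {c.cluster_id for c in clusters}
        assert not ids & {"decoy_chrM", "decoy_rand", "decoy_noref"}
        assert len(ids) == cohort["truth"]["gene"].nunique()

    def test_zero_overlap_config_gives_disjoint_windows(self, cohort):
        truth = cohort["truth"]
        for chrom, sub in truth.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            assert (np.diff(tss) >= 2000).all()

    def test_nested_fraction_plants_nested_pairs(self):
        cfg = SimulationConfig(n_genes=200, nested_fraction=0.1, seed=5)
        bundle = generate_all(cfg)
        truth = bundle["truth"].set_index("gene")
        nested = truth[truth.index.str.startswith("nest")]
        # binomial expectation 20, tolerate 3 sd (deterministic rounding here)
        assert abs(len(nested) - 20) <= 3 * np.sqrt(200 * 0.1 * 0.9)
        hosts = truth[~truth.index.str.startswith(("nest", "ovlp"))]
        for gene, row in nested.iterrows():
            host = hosts[
                (hosts["chrom"] == row["chrom"])
                & (hosts["body_start"] <= row["body_start"])
                & (hosts["body_end"] >= row["body_end"])
            ]
            assert len(host) >= 1


class TestMarkData:
    def test_positive_counts_well_separated_from_negatives(self, cohort):
        truth = cohort["truth"]
        states = truth_state_matrix(truth)
        counts = cohort["gene_counts"]
        for mark_i, mark in enumerate(("H3K27me3", "S5p", "S7p")):
            for tp in TIMEPOINTS:
                pos_genes = states.index[states[tp].map(lambda s: STATE_MARKS[s][mark_i])]
                sub = counts[(counts["mark"] == mark) & (counts["timepoint"] == tp)]
                sub = sub.set_index("gene")["count"]
                assert sub.loc[pos_genes].min() >= 1
                # decoy regions carry zero counts by construction
                assert (
                    sub.loc[sub.index.difference(pos_genes)].median()
                    < sub.loc[pos_genes].min()
                )

    def test_broad_regions_at_always_poised_promoters(self, cohort):
        regs = cohort["regions"][("H3K27me3", "ESC")]
        widths = (regs["end"] - regs["start"]).to_numpy()
        cfg = cohort["config"]
        broad = widths[widths > cfg.region_width_max]
        narrow = widths[widths <= cfg.region_width_max]
        assert len(broad) > 0
        ratio = np.median(broad) / np.median(narrow)
        assert ratio == pytest.approx(cfg.broad_width_factor, rel=0.25)

    def test_all_silent_cohort_has_no_overlapping_promoters(self):
        cfg = SimulationConfig(
            n_genes=40,
            seed=9,
            decoy_region_prob=0.0,
            group_fractions={"always_inactive": 1.0},
        )
        bundle = generate_all(cfg)
        assert len(bundle["regions"][("S5p", "ESC")]) == 0
        with pytest.raises(ValueError, match="no overlapping genes"):
            positivity_threshold([])


class TestTracksAndRanks:
    def test_cgi_coverage_highest_for_always_poised(self, cohort):
        from promoterpoise.features import cgi_coverage
        from promoterpoise.intervals import GenomicInterval, by_chrom

        truth = cohort["truth"]
        cgi = by_chrom(cohort["cgi"])
        cov = {}
        for group in ("always_prcs5p", "always_inactive"):
            vals = []
            for g in truth[truth["archetype"] == group].itertuples():
                s, e = cgi.get(g.chrom, (np.array([]), np.array([])))
                win = GenomicInterval(g.chrom, max(0, g.tss - 1000), g.tss + 1000)
                vals.append(cgi_coverage(win, s, e))
            cov[group] = np.mean(vals)
        assert cov["always_prcs5p"] > cov["always_inactive"]

    def test_rank_bias_favors_poised_tfs_in_non_neuronal_conversions(self, cohort):
        ranks = cohort["ranks"]
        truth = cohort["truth"].set_index("gene")
        nn = ranks[ranks["conversion"] == "cardiomyocyte"].set_index("tf")
        poised = nn.loc[nn.index[truth.loc[nn.index, "archetype"] == "always_prcs5p"]]
        other = nn.loc[nn.index[truth.loc[nn.index, "archetype"] == "always_inactive"]]
        assert poised["rank"].mean() < other["rank"].mean()

    def test_ranks_within_bounds(self, cohort):
        ranks = cohort["ranks"]["rank"]
        assert ranks.min() >= 1
        assert ranks.max() <= cohort["config"].max_rank


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(group_fractions={"always_active": 1.2}).validate()
    with pytest.raises(ValueError):
        SimulationConfig(group_fractions={"bogus": 0.1}).validate()
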