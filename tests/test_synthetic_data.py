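"""Ground-truth generators: sites, communities, sequences, qPCR tables."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bficomm.community_structure import pairwise_dissimilarity
from bficomm.sequence_properties import gc_content, gravy
from bficomm.sequence_units import build_aav_matrix, translate
from bficomm.synthetic_data import (
    FOUR_SEASONS,
    SimulationConfig,
    calibrate_niche_breadth,
    feature_sequences,
    generate_communities,
    generate_qpcr_table,
    generate_sequences,
    generate_sites,
    qpcr_sites,
    sites_to_metadata,
)


class TestGenerateSites:
    def test_bfi_span_and_geology_terciles(self, sites):
        bfis = sorted({s.bfi for s in sites})
        assert bfis[0] == pytest.approx(0.23)
        assert bfis[-1] == pytest.approx(0.95)
        by_geo = {}
        for s in sites:
            by_geo.setdefault(s.geology, set()).add(s.bfi)
        assert max(by_geo["clay"]) < min(by_geo["greensand"])
        assert max(by_geo["greensand"]) < min(by_geo["chalk"])

    def test_full_factorial_layout(self, sites, default_config):
        cfg = default_config
        assert len(sites) == cfg.n_sites * len(cfg.seasons) * cfg.n_replicates
        ids = {(s.site_id, s.season, s.replicate) for s in sites}
        assert len(ids) == len(sites)  # unique key

    def test_degenerate_range_rejected(self):
        cfg = SimulationConfig(n_sites=2, bfi_range=(0.5, 0.5))
        with pytest.raises(ValueError, match="degenerate"):
            generate_sites(cfg)

    def test_deterministic(self, default_config):
        a = sites_to_metadata(generate_sites(default_config))
        b = sites_to_metadata(generate_sites(default_config))
        pd.testing.assert_frame_equal(a, b)

    def test_qpcr_design_covers_four_seasons(self, default_config):
        sites = qpcr_sites(default_config)
        assert len(sites) == 9 * 4 * 3
        assert {s.season for s in sites} == set(FOUR_SEASONS)


class TestGenerateCommunities:
    def test_54_sample_columns(self, sites, default_config):
        com = generate_communities(sites, default_config)
        assert com.counts.shape[1] == 54
        assert (com.counts.to_numpy() >= 0).all()

    def test_deterministic_given_seed(self, sites, default_config):
        a = generate_communities(sites, default_config)
        b = generate_communities(sites, default_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_wide_niche_limit_removes_turnover(self, sites, default_config):
        cfg = replace(default_config, niche_breadth=50.0, gamma_richness=200)
        com = generate_communities(sites, cfg)
        pairs = pairwise_dissimilarity(com.counts)
        meta = sites_to_metadata(sites)
        site = meta.set_index("sample_id")["site_id"]
        within = pairs["sample_i"].map(site) == pairs["sample_j"].map(site)
        # all sites share one pool: between-site dissimilarity equals the
        # within-site (replicate) sampling noise
        between = pairs.loc[~within, "beta_sor"].mean()
        baseline = pairs.loc[within, "beta_sor"].mean()
        assert between == pytest.approx(baseline, rel=0.1)

    def test_narrower_niche_means_faster_turnover(self, sites, default_config):
        wide = generate_communities(
            sites, replace(default_config, niche_breadth=1.0)
        )
        narrow = generate_communities(
            sites, replace(default_config, niche_breadth=0.08)
        )
        assert (
            pairwise_dissimilarity(narrow.counts)["beta_sor"].mean()
            > pairwise_dissimilarity(wide.counts)["beta_sor"].mean()
        )

    def test_richness_precondition(self, sites, default_config):
        with pytest.raises(ValueError, match="gamma_richness"):
            generate_communities(
                sites, replace(default_config, gamma_richness=5)
            )

    def test_calibration_is_monotone_in_rate(self, default_config):
        bfis = np.linspace(0.23, 0.95, 9)
        s_fast = calibrate_niche_breadth(4.0, bfis, (0.23, 0.95))
        s_slow = calibrate_niche_breadth(1.5, bfis, (0.23, 0.95))
        assert s_fast < s_slow  # faster decay needs narrower niches


@pytest.fixture(scope="module")
def seqset(small_config):
    sites = generate_sites(small_config)
    com = generate_communities(sites, small_config)
    return com, generate_sequences(com, small_config)


class TestGenerateSequences:
    def test_reads_match_counts_and_translate_cleanly(self, seqset):
        com, seqs = seqset
        assert len(seqs.records) == com.counts.to_numpy().sum()
        for nt in seqs.records["nt"].unique():
            protein = translate(nt)  # raises on stops / bad frame
            assert len(protein) > 0
            assert len(nt) % 3 == 0

    def test_synonymous_variants_collapse_to_one_aav(self, seqset, small_config):
        com, seqs = seqset
        clusters, m = build_aav_matrix(seqs)
        # multi-variant clusters exist, and each pair is strictly synonymous
        multi = [c for c in clusters if len(c.member_nt) > 1]
        assert multi
        for c in multi:
            assert {translate(nt) for nt in c.member_nt} == {c.protein}
        # AAV count equals the number of distinct proteins among the
        # emitted species (nearby optima can yield identical proteins)
        variants = feature_sequences(com, small_config)
        present = com.counts.index[com.counts.sum(axis=1) > 0]
        distinct = {translate(variants[f][0]) for f in present}
        assert len(clusters) == len(distinct)

    def test_gc_trend_follows_configured_slope(self, small_config):
        sites = generate_sites(small_config)
        com = generate_communities(sites, small_config)

        def per_feature_gc_slope(cfg):
            variants = feature_sequences(com, cfg)
            mus = com.feature_optima.to_numpy(dtype=float)
            gcs = np.array([gc_content(v[0]) for v in variants.values()])
            return np.polyfit(mus, gcs, 1)[0], gcs

        # zero slope: GC spread across features is quantisation only
        slope0, gcs0 = per_feature_gc_slope(replace(small_config, gc_slope=0.0))
        assert abs(slope0) < 0.01
        assert np.std(gcs0) < 0.02
        # negative slope: species GC declines along the optimum axis
        slope, _ = per_feature_gc_slope(small_config)
        assert slope == pytest.approx(small_config.gc_slope, rel=0.25)

    def test_empty_community_rejected(self, small_config):
        sites = generate_sites(small_config)
        com = generate_communities(sites, small_config)
        empty = replace(com, counts=com.counts.iloc[0:0])
        with pytest.raises(ValueError, match="empty"):
            generate_sequences(empty, small_config)

    def test_infeasible_property_combination_errors(self, small_config):
        sites = generate_sites(small_config)
        com = generate_communities(sites, small_config)
        bad = replace(small_config, gc_intercept=0.99, gc_slope=0.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_sequences(com, bad)


class TestGenerateQpcr:
    def test_deterministic_and_long_format(self, default_config):
        sites = qpcr_sites(default_config)
        a = generate_qpcr_table(sites, default_config)
        b = generate_qpcr_table(sites, default_config)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["gene"]) == {
            "aoa_amoA", "aob_amoA", "hzo", "nirS", "mcrA", "bac_16S"
        }
        assert len(a) == len(sites) * 6
        assert (a["copies"] >= 0).all()

    def test_null_slope_yields_flat_proportions(self, default_config):
        from bficomm.group_models import compute_group_proportions, fit_beta

        cfg = replace(default_config, beta_coefs=(0.5, 0.0))
        sites = qpcr_sites(cfg)
        q = generate_qpcr_table(sites, cfg)
        props = compute_group_proportions(q)
        meta = sites_to_metadata(sites).set_index("sample_id")
        data = meta.loc[props.index]
        fit = fit_beta(props["p_aoa"].to_numpy(), data, terms=("bfi",))
        assert fit.odds_scale["bfi"] == pytest.approx(1.0, abs=0.4)

    def test_bad_precision_rejected(self):
        with pytest.raises(ValueError, match="precision_phi"):
            SimulationConfig(precision_phi=0.0)
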