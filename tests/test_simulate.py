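"""Generator correctness: structure, determinism, and marginal statistics."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from ceranet.config import SimConfig
from ceranet.errors import ValidationError
from ceranet.simulate import (
    generate_annotation,
    generate_coding_calls,
    generate_dataset,
    generate_expression,
    generate_interactions,
    plant_triads,
    support_pool_ids,
)
from conftest import small_sim_config


class TestAnnotation:
    def test_empty_feature_set(self):
        cfg = small_sim_config(n_mrna=0, n_lncrna=0, n_planted_triads=0)
        records, sizes = generate_annotation(cfg)
        assert records == []
        assert len(sizes) == cfg.n_chromosomes

    def test_counts_match_config(self):
        cfg = small_sim_config(seed=1, n_mrna=50, n_lncrna=20)
        records, _ = generate_annotation(cfg)
        by_type = pd.Series([r.biotype for r in records]).value_counts()
        assert by_type["mRNA"] == 50
        assert by_type["lncRNA"] == 20

    def test_structure_invariants(self, small_dataset):
        cfg = small_dataset.config
        for r in small_dataset.annotation:
            assert 1 <= r.start <= r.end <= cfg.chromosome_length
            assert r.length == sum(e - s + 1 for s, e in r.exons)
            prev_end = 0
            for s, e in r.exons:
                assert s > prev_end and r.start <= s <= e <= r.end
                prev_end = e
            if r.biotype == "mRNA":
                assert r.orf_length > 0
            else:
                assert 0 < r.orf_length < 300

    def test_determinism_and_seed_sensitivity(self):
        a1, _ = generate_annotation(small_sim_config(seed=1))
        a2, _ = generate_annotation(small_sim_config(seed=1))
        a3, _ = generate_annotation(small_sim_config(seed=2))
        assert a1 == a2
        assert a1 != a3

    def test_sizing_error(self):
        cfg = small_sim_config(chromosome_length=4000)
        with pytest.raises(Exception, match="chromosome|fit"):
            generate_annotation(cfg)


class TestExpression:
    def test_matrix_shapes(self, small_dataset):
        cfg = small_dataset.config
        n_samples = 3 * 2 * cfg.n_replicates_per_condition
        assert small_dataset.mrna_counts.shape == (cfg.n_mrna, n_samples)
        assert small_dataset.lncrna_counts.shape == (cfg.n_lncrna, n_samples)
        assert small_dataset.mirna_counts.shape == (cfg.n_mirna, n_samples)
        assert len(small_dataset.samples) == n_samples

    def test_no_signal_limit_means(self):
        """With beta=0, delta=0, phi=0 counts are Poisson around exp(a)."""
        cfg = small_sim_config(
            coupling_beta=0.0,
            condition_shift_delta=0.0,
            nb_dispersion_phi=0.0,
            background_de_fraction=0.0,
            baseline_log_mean_range=(4.0, 4.0),
            n_replicates_per_condition=30,
        )
        ann, _ = generate_annotation(cfg)
        triads = plant_triads(cfg)
        mrna, *_ = generate_expression(ann, cfg, triads)
        mean = np.exp(4.0)
        n = mrna.shape[1]
        se = np.sqrt(mean / n)
        within = np.abs(mrna.mean(axis=1) - mean) < 3 * se
        assert within.mean() > 0.95

    def test_triad_correlation_signs(self):
        """Large-n sample correlations carry the planted sign structure."""
        cfg = small_sim_config(
            n_planted_triads=1,
            coupling_beta=1.5,
            condition_shift_delta=0.0,
            n_replicates_per_condition=40,
        )
        ann, _ = generate_annotation(cfg)
        triads = plant_triads(cfg)
        mrna, lnc, mir, _, _ = generate_expression(ann, cfg, triads)
        t = triads[0]
        from scipy.stats import pearsonr, spearmanr

        rho, _ = spearmanr(mir.loc[t.mirna_id], mrna.loc[t.mrna_id])
        r, _ = pearsonr(lnc.loc[t.lncrna_id], mrna.loc[t.mrna_id])
        assert rho < 0
        assert r > 0

    def test_nb_marginal_moments(self):
        """Non-triad features: var ~ mean + phi mean^2 at n ~ 10000 draws."""
        cfg = small_sim_config(
            n_mrna=5, n_lncrna=2, n_mirna=14, n_planted_triads=0,
            background_de_fraction=0.0,
            nb_dispersion_phi=0.1,
            baseline_log_mean_range=(4.0, 4.0),
            n_replicates_per_condition=1667,
        )
        ann, _ = generate_annotation(cfg)
        mrna, *_ = generate_expression(ann, cfg, [])
        x = mrna.to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        expected = m + 0.1 * m**2
        assert np.all(np.abs(v - expected) / expected < 0.15)

    def test_de_truth_covers_all_triad_members(self, small_dataset):
        de = small_dataset.truth.de_truth.set_index("feature_id")
        for t in small_dataset.triads:
            for fid in t.as_tuple():
                assert bool(de.loc[fid, "is_de"])

    def test_support_pool_never_de(self, small_dataset):
        de = small_dataset.truth.de_truth.set_index("feature_id")
        for mid in support_pool_ids(small_dataset.config):
            assert not bool(de.loc[mid, "is_de"])


class TestCodingCalls:
    def test_noiseless_and_inverted_limits(self, small_dataset):
        ann = small_dataset.annotation
        cfg0 = small_sim_config(coding_call_flip_rate=0.0)
        cfg1 = small_sim_config(coding_call_flip_rate=1.0)
        truth = {r.transcript_id: ("coding" if r.biotype == "mRNA" else "noncoding")
                 for r in ann}
        calls0 = generate_coding_calls(ann, cfg0)
        assert all(truth[t] == v for t, v in zip(calls0["transcript_id"], calls0["verdict"]))
        calls1 = generate_coding_calls(ann, cfg1)
        assert all(truth[t] != v for t, v in zip(calls1["transcript_id"], calls1["verdict"]))

    def test_flip_fraction_binomial(self):
        cfg = small_sim_config(
            seed=1, n_mrna=1000, n_lncrna=1000, n_mirna=40,
            n_planted_triads=8, n_chromosomes=20,
            coding_call_flip_rate=0.1,
        )
        ann, _ = generate_annotation(cfg)
        calls = generate_coding_calls(ann, cfg)
        truth = {r.transcript_id: ("coding" if r.biotype == "mRNA" else "noncoding")
                 for r in ann}
        calls["error"] = [
            truth[t] != v for t, v in zip(calls["transcript_id"], calls["verdict"])
        ]
        n = len(ann)
        se = np.sqrt(0.1 * 0.9 / n)
        for _, grp in calls.groupby("tool"):
            assert abs(grp["error"].mean() - 0.1) < 3 * se


class TestInteractions:
    def test_planted_only(self):
        cfg = small_sim_config(
            n_planted_triads=5, background_interaction_rate=0.0, n_support_mirnas=0
        )
        ann, _ = generate_annotation(cfg)
        triads = plant_triads(cfg)
        lnc_tab, mrna_tab = generate_interactions(ann, triads, cfg)
        assert len(lnc_tab) == 5 and len(mrna_tab) == 5
        assert set(map(tuple, lnc_tab.itertuples(index=False))) == {
            (t.mirna_id, t.lncrna_id) for t in triads
        }

    def test_complete_bipartite(self):
        cfg = small_sim_config(
            n_mrna=10, n_lncrna=5, n_mirna=20, n_planted_triads=0,
            background_interaction_rate=1.0, n_support_mirnas=0,
        )
        ann, _ = generate_annotation(cfg)
        lnc_tab, mrna_tab = generate_interactions(ann, [], cfg)
        assert len(lnc_tab) == 20 * 5
        assert len(mrna_tab) == 20 * 10

    def test_background_rate_binomial(self):
        cfg = small_sim_config(
            seed=1, n_mrna=10, n_lncrna=100, n_mirna=100, n_planted_triads=0,
            background_interaction_rate=0.05, n_support_mirnas=0,
            n_chromosomes=12,
        )
        ann, _ = generate_annotation(cfg)
        lnc_tab, _ = generate_interactions(ann, [], cfg)
        n_pairs = 100 * 100
        se = np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(len(lnc_tab) - 500) < 3 * se

    def test_planted_links_present(self, small_dataset):
        lnc_links = set(map(tuple, small_dataset.mirna_lncrna.itertuples(index=False)))
        mrna_links = set(map(tuple, small_dataset.mirna_mrna.itertuples(index=False)))
        for t in small_dataset.triads:
            assert (t.mirna_id, t.lncrna_id) in lnc_links
            assert (t.mirna_id, t.mrna_id) in mrna_links


class TestDataset:
    def test_field_for_field_determinism(self, small_config, small_dataset):
        other = generate_dataset(small_config)
        assert other.annotation == small_dataset.annotation
        assert other.triads == small_dataset.triads
        pdt.assert_frame_equal(other.mrna_counts, small_dataset.mrna_counts)
        pdt.assert_frame_equal(other.lncrna_counts, small_dataset.lncrna_counts)
        pdt.assert_frame_equal(other.mirna_counts, small_dataset.mirna_counts)
        pdt.assert_frame_equal(other.coding_calls, small_dataset.coding_calls)
        pdt.assert_frame_equal(other.mirna_lncrna, small_dataset.mirna_lncrna)
        pdt.assert_frame_equal(other.term_map, small_dataset.term_map)
        assert other.known_lncrna_ids == small_dataset.known_lncrna_ids

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimConfig(n_planted_triads=1000).validate()
        with pytest.raises(ValidationError):
            SimConfig(nb_dispersion_phi=-0.5).validate()
        with pytest.raises(ValidationError):
            SimConfig(background_interaction_rate=1.5).validate()
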