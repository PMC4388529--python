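"""Synthetic cohort generators: interactome, genome map, CN, expression, survival."""

import math

import networkx as nx
import numpy as np
import pytest

from cnmod.segments import gene_level_calls, recurrence_filter
from cnmod.synthetic import (
    SyntheticConfig,
    generate_genome_map,
    generate_interactome,
    simulate_cn_profiles,
    simulate_expression,
    simulate_survival,
)


def small_cfg(**overrides):
    base = dict(
        n_genes=100, n_samples=12, n_modules=5, module_size=8,
        n_chromosomes=4, seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="penetrance"):
            small_cfg(alteration_penetrance=1.5)

    def test_modules_must_fit(self):
        with pytest.raises(ValueError):
            small_cfg(n_modules=20, module_size=10)


class TestInteractome:
    def test_size_contract_and_labels(self):
        cfg = small_cfg(n_modules=5, module_size=12, within_module_edge_prob=0.8, seed=1)
        g, truth = generate_interactome(cfg)
        assert g.number_of_nodes() == 100
        assert len(set(truth.planted_module_membership.values())) == 5
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0
        # at least the planted within-module edges beyond the background
        planted_edges = sum(
            1 for u, v in g.edges()
            if truth.planted_module_membership.get(u)
            == truth.planted_module_membership.get(v)
            and u in truth.planted_module_membership
        )
        assert planted_edges >= 5 * math.comb(12, 2) * 0.5

    def test_same_seed_identical_edge_sets(self):
        cfg = small_cfg(seed=3)
        g1, t1 = generate_interactome(cfg)
        g2, t2 = generate_interactome(small_cfg(seed=3))
        assert set(g1.edges()) == set(g2.edges())
        assert t1.planted_module_membership == t2.planted_module_membership

    def test_full_density_modules_are_cliques(self):
        cfg = small_cfg(within_module_edge_prob=1.0, module_size=4, n_modules=3)
        g, truth = generate_interactome(cfg)
        for m in range(3):
            members = [
                gnm for gnm, mm in truth.planted_module_membership.items() if mm == m
            ]
            assert g.subgraph(members).number_of_edges() == 6  # all C(4,2) pairs

    def test_heavy_tailed_background_degrees(self):
        g, _ = generate_interactome(small_cfg(n_genes=200, seed=5))
        degrees = sorted(d for _, d in g.degree())
        assert degrees[-1] >= 3 * degrees[len(degrees) // 2]

    def test_causal_and_risk_genes_within_plant(self):
        _, truth = generate_interactome(small_cfg())
        assert truth.causal_genes <= set(truth.planted_module_membership)
        assert truth.risk_genes <= truth.causal_genes
        assert truth.risk_genes  # at least one loss-direction module exists


class TestGenomeMap:
    def test_sorted_disjoint_per_chromosome(self):
        gm = generate_genome_map(small_cfg())
        assert gm["chrom"].nunique() == 4
        for _, sub in gm.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
            assert (starts < ends).all()

    def test_module_blocks_contiguous_on_one_chromosome(self):
        cfg = small_cfg()
        gm = generate_genome_map(cfg)
        _, truth = generate_interactome(cfg)
        gm_idx = gm.reset_index(drop=True)
        for m in set(truth.planted_module_membership.values()):
            members = [
                g for g, mm in truth.planted_module_membership.items() if mm == m
            ]
            rows = gm_idx[gm_idx["gene"].isin(members)]
            assert rows["chrom"].nunique() == 1
            assert list(rows.index) == list(range(rows.index[0], rows.index[-1] + 1))

    def test_round_trip_lossless(self, tmp_path):
        from cnmod.io import read_genome_map, write_genome_map

        gm = generate_genome_map(small_cfg())
        write_genome_map(gm, tmp_path / "gm.tsv")
        back = read_genome_map(tmp_path / "gm.tsv")
        assert back.equals(gm)


class TestCnProfiles:
    def test_full_penetrance_every_sample_carries_every_event(self):
        cfg = small_cfg(alteration_penetrance=1.0, n_samples=10)
        g, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        profiles = simulate_cn_profiles(cfg, gm, truth)
        cm = gene_level_calls(profiles, gm)
        for gene, m in truth.planted_module_membership.items():
            expected = 1 if truth.module_directions[m] == "gain" else -1
            assert (cm.calls.loc[gene] == expected).all()

    def test_zero_penetrance_yields_no_recurrent_genes(self):
        cfg = small_cfg(alteration_penetrance=0.0)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        cm = gene_level_calls(simulate_cn_profiles(cfg, gm, truth), gm)
        rec = recurrence_filter(cm)
        assert rec.gain_genes == set() and rec.loss_genes == set()

    def test_carrier_counts_match_golden_and_binomial_interval(self):
        """Penetrance 0.5 over 40 samples: frozen per-module carrier counts
        from this seed, each inside the binomial 95% interval around 20."""
        cfg = small_cfg(alteration_penetrance=0.5, n_samples=40, seed=1)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        cm = gene_level_calls(simulate_cn_profiles(cfg, gm, truth), gm)
        counts = []
        for m in sorted(truth.module_directions):
            gene = next(
                g for g, mm in truth.planted_module_membership.items() if mm == m
            )
            expected = 1 if truth.module_directions[m] == "gain" else -1
            counts.append(int((cm.calls.loc[gene] == expected).sum()))
        assert counts == [24, 22, 18, 21, 24]  # golden: regenerate-and-count
        lo, hi = 20 - 1.96 * math.sqrt(40 * 0.25), 20 + 1.96 * math.sqrt(40 * 0.25)
        assert all(lo <= c <= hi for c in counts)

    def test_ploidy_distribution_near_target(self):
        cfg = small_cfg(n_samples=200, seed=9)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        profiles = simulate_cn_profiles(cfg, gm, truth)
        ploidies = np.array([p.ploidy for p in profiles])
        assert ploidies.min() >= 1.5
        assert abs(ploidies.mean() - 2.8) < 0.1

    def test_decoy_segments_below_marker_threshold_exist(self):
        cfg = small_cfg()
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        profiles = simulate_cn_profiles(cfg, gm, truth)
        decoys = [
            s for p in profiles for s in p.segments
            if s.n_markers < 10 and abs(s.total_cn - p.ploidy) > 0.9
        ]
        assert decoys  # sub-threshold, high-amplitude segments are planted

    def test_same_seed_bit_identical(self):
        cfg = small_cfg(seed=11)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        a = simulate_cn_profiles(cfg, gm, truth)
        b = simulate_cn_profiles(cfg, gm, truth)
        assert [(s.interval, s.total_cn, s.n_markers) for p in a for s in p.segments] == [
            (s.interval, s.total_cn, s.n_markers) for p in b for s in p.segments
        ]


class TestExpression:
    def _cohort(self, **overrides):
        cfg = small_cfg(**overrides)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        cm = gene_level_calls(simulate_cn_profiles(cfg, gm, truth), gm)
        return cfg, truth, cm

    def test_noiseless_causal_gene_correlates_perfectly(self):
        cfg, truth, cm = self._cohort(noise_sd=1e-12, alteration_penetrance=0.8)
        expr = simulate_expression(cm, truth, cfg)
        gene = sorted(truth.causal_genes)[0]
        cn = cm.cn.loc[gene]
        if cn.std() > 0:
            r = np.corrcoef(cn, expr.loc[gene])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_noncausal_genes_at_null_correlation_magnitude(self):
        cfg, truth, cm = self._cohort(n_samples=40, seed=13)
        expr = simulate_expression(cm, truth, cfg)
        null_genes = [
            g for g in cm.genes
            if g not in truth.causal_genes and cm.cn.loc[g].std() > 0
        ]
        rs = [
            abs(np.corrcoef(cm.cn.loc[g], expr.loc[g])[0, 1]) for g in null_genes
        ]
        # E|r| under the null ~ sqrt(2/(pi*(n-1))) ~ 0.128 at n = 40
        expected = math.sqrt(2 / (math.pi * 39))
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)

    def test_same_seed_reproducible(self):
        cfg, truth, cm = self._cohort(seed=15)
        a = simulate_expression(cm, truth, cfg)
        b = simulate_expression(cm, truth, cfg)
        assert a.equals(b)


class TestSurvival:
    def _cohort(self, **overrides):
        cfg = small_cfg(**overrides)
        _, truth = generate_interactome(cfg)
        gm = generate_genome_map(cfg)
        cm = gene_level_calls(simulate_cn_profiles(cfg, gm, truth), gm)
        return cfg, truth, cm

    def test_full_censoring(self):
        cfg, truth, cm = self._cohort(censor_rate=1.0)
        surv = simulate_survival(cm, truth, cfg)
        assert (surv["event"] == 0).all()

    def test_no_censoring(self):
        cfg, truth, cm = self._cohort(censor_rate=0.0)
        surv = simulate_survival(cm, truth, cfg)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_risk_group_dies_earlier_with_large_hazard_ratio(self):
        cfg, truth, cm = self._cohort(
            hazard_ratio_loss=5.0, alteration_penetrance=0.5,
            n_samples=40, censor_rate=0.0,
        )
        wins = 0
        n_sims = 30
        for s in range(n_sims):
            cfg_s = small_cfg(
                hazard_ratio_loss=5.0, alteration_penetrance=0.5,
                n_samples=40, censor_rate=0.0, seed=100 + s,
            )
            surv = simulate_survival(cm, truth, cfg_s)
            at_risk = (cm.calls.loc[sorted(truth.risk_genes)] == -1).any(axis=0)
            risk_median = surv.set_index("sample").loc[at_risk[at_risk].index, "time"].median()
            safe_median = surv.set_index("sample").loc[at_risk[~at_risk].index, "time"].median()
            wins += risk_median < safe_median
        assert wins / n_sims >= 0.95
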