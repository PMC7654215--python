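"""Synthetic study-universe generators: determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cpnet import centrality as ct
from cpnet import graphcore as gc
from cpnet.config import SyntheticConfig
from cpnet.errors import CpnetWarning, DegenerateError, InputError
from cpnet import synth


class TestConfig:
    def test_validation(self):
        with pytest.raises(InputError):
            SyntheticConfig(n_genes=0)
        with pytest.raises(InputError):
            SyntheticConfig(frac_expressed=1.5)
        with pytest.raises(InputError):
            SyntheticConfig(censoring_rate=1.0)
        with pytest.raises(InputError):
            SyntheticConfig(n_proteins=50, planted_module_size=50)

    def test_substreams_are_independent(self, small_cfg):
        a = small_cfg.rng("expression").random(5)
        b = small_cfg.rng("interactome").random(5)
        assert not np.allclose(a, b)
        assert np.allclose(a, small_cfg.rng("expression").random(5))


class TestExpression:
    def test_seeded_determinism(self, small_cfg):
        a = synth.gen_expression_dataset(small_cfg)
        b = synth.gen_expression_dataset(small_cfg)
        assert np.array_equal(a.intensities, b.intensities)
        assert a.meta == b.meta

    def test_planted_count_is_exact(self):
        cfg = SyntheticConfig(seed=1, n_genes=100, frac_expressed=0.2,
                              n_proteins=60, planted_module_size=5)
        expr = synth.gen_expression_dataset(cfg)
        assert len(expr.meta["expressed"]) == 20

    def test_no_expressed_genes_warns(self):
        cfg = SyntheticConfig(seed=1, n_genes=10, frac_expressed=0.0,
                              n_proteins=8, planted_module_size=2)
        with pytest.warns(CpnetWarning):
            expr = synth.gen_expression_dataset(cfg)
        assert expr.meta["expressed"] == []

    def test_planted_genes_rank_higher_across_seeds(self):
        # Monte-Carlo check against the generator's own construction
        diffs = []
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed, n_genes=60, n_replicates=3,
                                  frac_expressed=0.2, n_proteins=40,
                                  planted_module_size=3)
            expr = synth.gen_expression_dataset(cfg)
            ranks = np.column_stack(
                [rankdata(-expr.intensities[:, j]) for j in range(3)]
            ).mean(axis=1)
            planted = np.isin(expr.gene_ids, expr.meta["expressed"])
            diffs.append(ranks[~planted].mean() - ranks[planted].mean())
        assert np.mean(diffs) > 0


class TestInteractome:
    def test_seeded_determinism(self, small_cfg):
        a = synth.gen_interactome(small_cfg)
        b = synth.gen_interactome(small_cfg)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_module_is_pairwise_connected(self, small_cfg):
        table = synth.gen_interactome(small_cfg)
        module = table.meta["module"]
        pairs = {frozenset(p) for p in zip(table.edges["node_a"], table.edges["node_b"])}
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                assert frozenset((a, b)) in pairs

    def test_module_mean_degree_exceeds_network_mean(self):
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed, n_genes=200, n_proteins=120,
                                  planted_module_size=6, module_spokes=12)
            table = synth.gen_interactome(cfg)
            net = gc.build_network(table, 0.0)
            records = ct.compute_centralities(net)
            by = records.set_index("node")["degree"]
            module_mean = by[table.meta["module"]].mean()
            assert module_mean > by.mean()

    def test_degenerate_attachment_raises(self):
        cfg = SyntheticConfig(seed=1, n_genes=20, n_proteins=10,
                              attachment_parameter=10, planted_module_size=3)
        with pytest.raises(DegenerateError):
            synth.gen_interactome(cfg)


class TestChemicalLinks:
    def test_exact_edge_count(self, small_cfg):
        table = synth.gen_interactome(small_cfg)
        out = synth.gen_chemical_links(table, ["Rsv", "Doxo"], 5, small_cfg)
        assert len(out) == len(table) + 10

    def test_full_overlap_shares_all_targets(self, small_cfg):
        table = synth.gen_interactome(small_cfg)
        out = synth.gen_chemical_links(table, ["Rsv", "Doxo"], 5, small_cfg, overlap=5)
        targets = out.meta["chemical_targets"]
        assert set(targets["Rsv"]) == set(targets["Doxo"])

    def test_unknown_chemical_raises(self, small_cfg):
        table = synth.gen_interactome(small_cfg)
        with pytest.raises(InputError):
            synth.gen_chemical_links(table, ["Mystery"], 5, small_cfg)

    def test_module_targets_included(self, small_cfg):
        table = synth.gen_interactome(small_cfg)
        out = synth.gen_chemical_links(
            table, ["Rsv"], small_cfg.targets_per_chemical, small_cfg
        )
        assert set(table.meta["module"]) <= set(out.meta["chemical_targets"]["Rsv"])


class TestDiseaseTable:
    def test_max_cutoff_keeps_only_module(self, small_cfg):
        table = synth.gen_disease_table(small_cfg.protein_ids, small_cfg)
        selected = gc.select_disease_genes(table, 1.0, 1000)
        assert set(selected) == set(table.meta["module"])

    def test_seeded_determinism(self, small_cfg):
        a = synth.gen_disease_table(small_cfg.protein_ids, small_cfg)
        b = synth.gen_disease_table(small_cfg.protein_ids, small_cfg)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_top_k_size_rule(self, small_cfg):
        table = synth.gen_disease_table(small_cfg.protein_ids, small_cfg)
        passing = int((table.rows["confidence"] >= 0.5).sum())
        for k in (3, passing, passing + 50):
            assert len(gc.select_disease_genes(table, 0.5, k)) == min(k, passing)


class TestSurvivalCohort:
    def test_zero_censoring_no_censored_records(self):
        cfg = SyntheticConfig(seed=2, n_patients=80, censoring_rate=0.0)
        tab = synth.gen_survival_cohort(["g1", "g2"], ["g1"], cfg)
        assert (tab.data["event"] == 1).all()

    def test_null_hazard_p_uniform(self):
        from scipy.stats import kstest

        from cpnet.survival import km_screen

        ps = []
        for seed in range(200):
            cfg = SyntheticConfig(seed=seed, n_patients=100, planted_log_hazard=0.0)
            tab = synth.gen_survival_cohort(["g"], ["g"], cfg)
            ps.append(km_screen(tab, ["g"]).loc[0, "p_value"])
        assert kstest(ps, "uniform").pvalue > 0.001

    def test_planted_gene_power(self):
        from cpnet.survival import km_screen

        hits = 0
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed, n_patients=400, planted_log_hazard=1.0)
            tab = synth.gen_survival_cohort(["g"], ["g"], cfg)
            hits += bool(km_screen(tab, ["g"]).loc[0, "significant"])
        assert hits >= 45  # >= 90% of 50 seeds

    def test_planted_must_be_subset(self, small_cfg):
        with pytest.raises(InputError):
            synth.gen_survival_cohort(["g1"], ["other"], small_cfg)


class TestMorphometry:
    def test_record_count_and_determinism(self, small_cfg):
        recs = synth.gen_morphometry(small_cfg, {"N": 0.5, "LR": 0.5})
        assert len(recs) == small_cfg.n_nuclei
        again = synth.gen_morphometry(small_cfg, {"N": 0.5, "LR": 0.5})
        assert [(r.area, r.nii) for r in recs] == [(r.area, r.nii) for r in again]

    def test_fractions_must_sum_to_one(self, small_cfg):
        with pytest.raises(InputError):
            synth.gen_morphometry(small_cfg, {"N": 0.5, "LR": 0.4})

    def test_pure_control_classified_normal(self):
        from cpnet.morphometry import classify_nuclei

        cfg = SyntheticConfig(seed=8, n_nuclei=300)
        control = synth.gen_morphometry(cfg, {"N": 1.0})
        classed = classify_nuclei(control, control)
        frac_n = sum(r.label == "N" for r in classed) / len(classed)
        assert frac_n >= 0.95


class TestPathwaysAndRegulation:
    def test_every_module_gene_in_some_pathway(self, small_cfg):
        coll = synth.gen_pathways(small_cfg)
        module = synth.planted_truth(small_cfg)["module"]
        union = coll.union()
        assert set(module) <= union
        for name in coll.sets:
            assert module[0] in coll.sets[name]

    def test_regulation_marks_module_up(self, small_cfg):
        reg = synth.gen_regulation(small_cfg)
        module = synth.planted_truth(small_cfg)["module"]
        assert all(reg[g] == "up" for g in module)
        assert set(reg.values()) <= {"up", "down", "none"}


class TestRoundTrips:
    def test_generated_tables_round_trip_through_netio(self, small_cfg, tmp_path):
        from cpnet import netio

        table = synth.gen_interactome(small_cfg)
        table = synth.gen_chemical_links(table, ["Rsv"], 4, small_cfg)
        p = tmp_path / "edges.tsv"
        netio.write_edge_table(table, p)
        back = netio.read_edge_table(p)
        assert back.nodes == table.nodes
        assert len(back) == len(table)

        disease = synth.gen_disease_table(small_cfg.protein_ids, small_cfg)
        dp = tmp_path / "disease.tsv"
        netio.write_disease_table(disease, dp)
        assert len(netio.read_disease_table(dp)) == len(disease)

        gmt = synth.gen_pathways(small_cfg)
        gp = tmp_path / "sets.gmt"
        netio.write_gmt(gmt, gp)
        assert netio.read_gmt(gp).sets == gmt.sets
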