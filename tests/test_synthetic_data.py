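import pytest

from csca import (
    SetDesign,
    SimSpec,
    SpecError,
    harmonize,
    make_deg_table,
    make_evidence_sets,
    make_ortholog_table,
    make_universe,
    overlap_test,
    paper_scenario,
    partition_degs,
)


class TestUniverse:
    def test_deterministic_unique_uppercase(self):
        a = make_universe(5, seed=1)
        assert a == make_universe(5, seed=1)
        assert len(set(a)) == 5
        assert all(s == s.upper() and s.startswith("SYNG") for s in a)

    def test_requested_size(self):
        assert len(make_universe(22000, seed=1)) == 22000

    def test_seeds_differ(self):
        assert make_universe(50, seed=1) != make_universe(50, seed=2)


class TestDegTable:
    def test_infeasible_spec_names_violated_inequality(self):
        with pytest.raises(SpecError, match="n_up"):
            SimSpec(universe_n=100, n_tested=50, n_deg_sig=10, n_up=8,
                    n_down=8, target_set_size=5, planted_overlap=2)
        with pytest.raises(SpecError, match="planted_overlap"):
            SimSpec(universe_n=100, n_tested=50, n_deg_sig=10, n_up=5,
                    n_down=5, target_set_size=5, planted_overlap=8)

    def test_partition_recovers_planted_up_down(self):
        spec = SimSpec(universe_n=1500, n_tested=600, n_deg_sig=200,
                       n_up=150, n_down=50, target_set_size=80,
                       planted_overlap=10, seed=11)
        records = make_deg_table(spec, make_universe(1500, 11))
        assert partition_degs(records).counts[:2] == (150, 50)

    def test_overlap_test_recovers_planted_intersection(self):
        spec = SimSpec(universe_n=1500, n_tested=600, n_deg_sig=200,
                       n_up=150, n_down=50, target_set_size=80,
                       planted_overlap=10, seed=11)
        universe = make_universe(1500, 11)
        records = make_deg_table(spec, universe)
        sig = partition_degs(records).significant
        r = overlap_test(sig, universe[:80], 1500)
        assert r.test.overlap_k == 10

    def test_extra_significant_genes_fall_below_lfc_threshold(self):
        spec = SimSpec(universe_n=500, n_tested=200, n_deg_sig=60, n_up=30,
                       n_down=20, target_set_size=30, planted_overlap=5,
                       seed=2)
        records = make_deg_table(spec, make_universe(500, 2))
        assert sum(r.significant for r in records) == 60
        p = partition_degs(records)
        assert p.counts[:2] == (30, 20)

    def test_rho_zero_draws_significant_genes_uniformly(self):
        spec = SimSpec(universe_n=400, n_tested=200, n_deg_sig=50, n_up=30,
                       n_down=20, target_set_size=100, planted_overlap=0.0,
                       seed=4)
        universe = make_universe(400, 4)
        records = make_deg_table(spec, universe)
        sig = partition_degs(records).significant
        assert len(sig) == 50  # overlap with the target is then free to vary

    def test_deterministic_per_seed(self):
        spec = SimSpec(universe_n=300, n_tested=100, n_deg_sig=30, n_up=20,
                       n_down=10, target_set_size=20, planted_overlap=4,
                       seed=6)
        universe = make_universe(300, 6)
        assert make_deg_table(spec, universe) == make_deg_table(spec, universe)


class TestEvidenceSets:
    def test_exact_pairwise_overlap(self):
        universe = make_universe(200, 3)
        a, b = make_evidence_sets(
            [SetDesign("a", "expression", 40), SetDesign("b", "expression", 30)],
            universe, seed=3, overlaps={("a", "b"): 10})
        assert (len(a.genes), len(b.genes)) == (40, 30)
        assert len(a.genes & b.genes) == 10

    def test_unrequested_pairs_disjoint(self):
        universe = make_universe(200, 3)
        sets = make_evidence_sets(
            [SetDesign("a", "gwas", 20), SetDesign("b", "gwas", 20),
             SetDesign("c", "causal", 20)],
            universe, seed=3, overlaps={("a", "b"): 5})
        assert not sets[0].genes & sets[2].genes
        assert not sets[1].genes & sets[2].genes

    def test_infeasible_design_rejected(self):
        universe = make_universe(30, 3)
        with pytest.raises(SpecError, match="universe"):
            make_evidence_sets([SetDesign("a", "gwas", 20),
                                SetDesign("b", "gwas", 20)], universe, seed=3)
        with pytest.raises(SpecError, match="shared"):
            make_evidence_sets(
                [SetDesign("a", "gwas", 4), SetDesign("b", "gwas", 10)],
                universe, seed=3, overlaps={("a", "b"): 6})


class TestOrthologTable:
    def test_fraction_one_maps_everything(self):
        genes = make_universe(100, 5)[:40]
        report = harmonize(genes, make_ortholog_table(genes, 1.0, seed=5))
        assert report.n_out == 40

    def test_fraction_zero_maps_nothing(self):
        genes = make_universe(100, 5)[:40]
        report = harmonize(genes, make_ortholog_table(genes, 0.0, seed=5))
        assert report.n_out == 0
        # both drop reasons exercised
        assert report.dropped_ambiguous and report.dropped_no_ortholog

    def test_exact_count_honored(self):
        genes = make_universe(2000, 7)[:1196]
        table = make_ortholog_table(genes, 1.0, seed=7, n_one2one=1157)
        assert harmonize(genes, table).n_out == 1157


class TestPaperScenario:
    def test_planted_counts_internally_consistent(self, scenario):
        assert len(scenario.deg_records) == scenario.planted["n_tested"]
        assert len(scenario.wr1_genes) == scenario.planted["n_wr1"]
        assert len(scenario.expression_genes) == \
            scenario.planted["n_expression_rule"]
        assert scenario.expression_genes <= scenario.wr1_genes
        assert len(scenario.scan_sets) == scenario.planted["n_scan_lists"]
        assert len(scenario.scan_sets[0].genes) == \
            scenario.planted["scan_hit_size"]

    def test_generated_files_parse_cleanly(self, scenario_dir):
        from csca import read_cuffdiff_diff, read_gmt, read_ortholog_table
        assert len(read_cuffdiff_diff(scenario_dir["deg"])) == 16384
        assert len(read_gmt(scenario_dir["compendium"])) == 7
        assert len(read_gmt(scenario_dir["scan"])) == 13
        assert read_ortholog_table(scenario_dir["orthologs"])

    def test_deterministic_per_seed(self):
        a = paper_scenario(3)
        b = paper_scenario(3)
        assert a.deg_records == b.deg_records
        assert a.universe == b.universe
        c = paper_scenario(4)
        assert a.deg_records != c.deg_records
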