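"""Generators: determinism, limiting behaviour, parameter recovery."""

import numpy as np
import pytest

from ricascade import (ConfigError, CrossArmConfig, CrossConfig,
                       ForagingConfig, PhenologySpeciesConfig, bout_constancy,
                       build_window, count_transitions, default_config,
                       ethological_ri, overlap_proportions, simulate_bouts,
                       simulate_crosses, simulate_dataset, simulate_phenology,
                       stage_ri, stage_success)


class TestDeterminism:
    def test_dataset_bit_identical_under_seed(self):
        a = simulate_dataset(default_config(seed=5))
        b = simulate_dataset(default_config(seed=5))
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_dataset(default_config(seed=5))
        b = simulate_dataset(default_config(seed=6))
        assert a != b


class TestPhenologyGenerator:
    def test_zero_variance_gives_closed_form_overlap(self, rng):
        cfgs = [PhenologySpeciesConfig("a", 10, 200, 0, 30, 0),
                PhenologySpeciesConfig("b", 10, 214, 0, 30, 0)]
        records = simulate_phenology(cfgs, rng)
        ov = overlap_proportions(build_window(records, "a"),
                                 build_window(records, "b"))
        # a: days 200..229, b: days 214..243 -> 16 shared of 30
        assert ov.shared_S == pytest.approx(16 / 30)

    def test_analytic_overlap_within_discretisation(self, rng):
        cfgs = [PhenologySpeciesConfig("a", 200, 200, 0.5, 30, 0.5),
                PhenologySpeciesConfig("b", 200, 214, 0.5, 30, 0.5)]
        records = simulate_phenology(cfgs, rng)
        ov = overlap_proportions(build_window(records, "a"),
                                 build_window(records, "b"))
        # generating windows overlap by ~16 of ~30 days; allow 1-day slack
        # on each window edge (4 edges -> ~4/30)
        assert abs(ov.shared_S - 16 / 30) < 4 / 30

    def test_empty_config_gives_empty_output(self, rng):
        assert simulate_phenology(
            [PhenologySpeciesConfig("a", 0, 200, 3, 14, 2)], rng) == []

    def test_invalid_sd_rejected(self):
        with pytest.raises(ConfigError):
            PhenologySpeciesConfig("a", 10, 200, -1, 14, 2)


class TestForagingGenerator:
    def test_kappa_one_perfect_constancy(self, rng):
        bouts = simulate_bouts(ForagingConfig("a", "b", n_bouts=100, kappa=1.0),
                               rng)
        table = count_transitions(bouts, "a", "b")
        assert table.interspecific == 0
        assert ethological_ri(table, "a") == 1.0
        for bout in bouts:
            if len(bout.visits) >= 2:
                assert bout_constancy(bout, "a", "b") == 1.0

    def test_kappa_zero_null_within_monte_carlo_error(self):
        # label-independent foraging: RI centred on 0
        ris = []
        rng = np.random.default_rng(101)
        for _ in range(500):
            bouts = simulate_bouts(
                ForagingConfig("a", "b", n_bouts=50, kappa=0.0,
                               abundance_a=0.5), rng)
            table = count_transitions(bouts, "a", "b")
            ris.append(ethological_ri(table, "a"))
        mean = np.mean(ris)
        se = np.std(ris, ddof=1) / np.sqrt(len(ris))
        assert abs(mean) < 3 * se

    def test_mean_bout_length(self):
        rng = np.random.default_rng(8)
        bouts = simulate_bouts(
            ForagingConfig("a", "b", n_bouts=3000, kappa=0.5, mean_visits=3.0),
            rng)
        lengths = [len(b.visits) for b in bouts]
        assert np.mean(lengths) == pytest.approx(3.0, abs=0.15)

    def test_invalid_kappa(self):
        with pytest.raises(ConfigError):
            ForagingConfig("a", "b", n_bouts=5, kappa=1.5)


class TestCrossGenerator:
    def test_nesting_invariant_by_construction(self, rng):
        cfg = CrossConfig("A", "B")
        pistils, fruits, seeds = simulate_crosses(cfg, rng)
        for p in pistils:
            assert p.tubes_in_ovary <= p.tubes_in_style <= p.tubes_on_stigma
        assert all(f.fruits_set <= f.flowers_treated for f in fruits)
        assert all(s.total_scored == 300 for s in seeds)

    def test_blocked_fruit_arm_gives_ri_one(self, rng):
        cfg = CrossConfig("A", "B", inter=CrossArmConfig(p_fruit=0.0))
        _, fruits, seeds = simulate_crosses(cfg, rng)
        succ = stage_success(fruits, "fruit", ("A", "B"))
        assert stage_ri(succ) == 1.0
        # no interspecific fruit -> no interspecific seed assay
        assert not [s for s in seeds if s.treatment == "inter_cross"]

    def test_null_crosses_stage_ri_within_3_se(self):
        # identical rates in both arms at every stage
        rng = np.random.default_rng(202)
        arm = CrossArmConfig(n_pistils=25, n_flowers=30)
        cfg = CrossConfig("A", "B", intra=arm, inter=arm)
        by_stage = {s: [] for s in ("style", "ovary", "fruit", "seed")}
        for _ in range(500):
            pistils, fruits, seeds = simulate_crosses(cfg, rng)
            sources = {"style": pistils, "ovary": pistils,
                       "fruit": fruits, "seed": seeds}
            for stage, data in sources.items():
                by_stage[stage].append(
                    stage_ri(stage_success(data, stage, ("A", "B"))))
        for stage, ris in by_stage.items():
            mean = np.mean(ris)
            se = np.std(ris, ddof=1) / np.sqrt(len(ris))
            assert abs(mean) < 3 * se, f"{stage}: mean {mean} vs SE {se}"

    def test_probability_validation(self):
        with pytest.raises(ConfigError):
            CrossArmConfig(p_fruit=1.2)
        with pytest.raises(ConfigError):
            CrossArmConfig(embryo_probs=(0.5, 0.5, 0.5, 0.5))


class TestDefaultStudy:
    def test_shared_intra_arm_per_maternal_species(self, default_dataset):
        fruits = default_dataset["fruits"]
        intra = [(f.maternal_species, f.paternal_species) for f in fruits
                 if f.treatment == "intra_cross"]
        # one intraspecific control per species, not per direction
        assert len(intra) == 3 * 50

    def test_three_record_types_schema_valid(self, default_dataset):
        assert {r.species for r in default_dataset["phenology"]} == \
            {"lim", "dav", "del"}
        assert default_dataset["pistils"] and default_dataset["seeds"]


class TestReferenceStudy:
    def test_array_totals(self, reference_tables):
        t = reference_tables["lim_dav"]
        assert (t.n_aa, t.n_bb, t.n_ab, t.n_ba) == (16, 14, 3, 1)
        t = reference_tables["lim_del"]
        assert (t.n_aa, t.n_bb, t.n_ab, t.n_ba) == (10, 13, 2, 2)

    def test_ladder_entries(self, published_ladders):
        assert published_ladders["lim x dav"]["phenology"] == 0.026
        assert published_ladders["dav x del"]["ethological"] is None

    def test_pollinator_cells_sum_to_totals(self, reference_study):
        for arr in reference_study["arrays"].values():
            for cell in ("n_aa", "n_bb", "n_ab", "n_ba"):
                assert sum(p[cell] for p in arr["pollinators"].values()) == \
                    arr["total"][cell]
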