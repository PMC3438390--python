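"""Colony simulator: determinism, meiosis model, dropout, sampling accuracy."""

import numpy as np
import pytest

from mhckit.model import Diplotype, genotype_from_diplotype, haplotypes_block_equal
from mhckit.regions import GENOTYPE_LOCI, Interval
from mhckit.simulate import (
    SimConfig,
    emit_observations,
    founder_weights,
    make_chimera,
    simulate_colony,
    simulate_meiosis,
    write_simulation,
)


class TestConfig:
    def test_rejects_tiny_colonies_and_bad_probabilities(self):
        with pytest.raises(ValueError):
            SimConfig(n_founders=1)
        with pytest.raises(ValueError):
            SimConfig(recomb_rate_per_meiosis=1.5)
        with pytest.raises(ValueError):
            SimConfig(breakpoint_weights=(0, 0, 0, 0))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_founders: 6\nn_generations: 3\nseed: 9\n"
            "breakpoint_weights: [1, 2, 3, 4]\n"
        )
        cfg = SimConfig.from_yaml(path)
        assert cfg.n_founders == 6 and cfg.breakpoint_weights == (1, 2, 3, 4)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_founders=8, n_generations=3, seed=7)
        for d in ("a", "b"):
            truth, records = simulate_colony(cfg)
            write_simulation(truth, records, tmp_path / d)
        for name in ("genotypes.tsv", "str_profiles.tsv", "pedigree.tsv",
                     "truth.json"):
            assert (tmp_path / "a" / name).read_text() == \
                (tmp_path / "b" / name).read_text()

    def test_different_seeds_differ(self):
        t1, _ = simulate_colony(SimConfig(n_founders=8, n_generations=3, seed=1))
        t2, _ = simulate_colony(SimConfig(n_founders=8, n_generations=3, seed=2))
        assert t1.diplotypes != t2.diplotypes


class TestMeiosis:
    def test_zero_rate_transmits_parental_haplotypes_only(self, pool):
        cfg = SimConfig(recomb_rate_per_meiosis=0.0, seed=0)
        rng = np.random.default_rng(0)
        parent = Diplotype(("3", "21"))
        for _ in range(200):
            hap_id, event, chimera = simulate_meiosis(parent, cfg, rng, pool)
            assert hap_id in parent.pair
            assert event is None and chimera is None

    def test_forced_crossover_of_21_and_26_reproduces_haplotype_22(self, pool):
        chim = make_chimera(pool.get("21"), pool.get("26"), Interval.A_B, "x")
        assert haplotypes_block_equal(chim, pool.get("22"))

    def test_crossover_rate_matches_binomial_expectation(self, pool):
        cfg = SimConfig(recomb_rate_per_meiosis=0.05, seed=0)
        rng = np.random.default_rng(12)
        parent = Diplotype(("3", "21"))
        n = 10_000
        hits = sum(
            simulate_meiosis(parent, cfg, rng, pool)[1] is not None
            for _ in range(n)
        )
        p = 0.05
        se = (p * (1 - p) / n) ** 0.5
        assert abs(hits / n - p) <= 3 * se + 1e-12

    def test_breakpoint_weights_steer_the_interval(self, pool):
        cfg = SimConfig(
            recomb_rate_per_meiosis=1.0, breakpoint_weights=(0, 0, 1, 0), seed=0
        )
        rng = np.random.default_rng(3)
        parent = Diplotype(("3", "21"))
        for _ in range(50):
            _, event, _ = simulate_meiosis(parent, cfg, rng, pool)
            assert event.interval is Interval.DR_DQ


class TestColony:
    def test_zero_rate_produces_no_crossover_events(self):
        truth, _ = simulate_colony(
            SimConfig(n_founders=10, n_generations=4,
                      recomb_rate_per_meiosis=0.0, seed=5)
        )
        assert truth.crossovers == []
        assert truth.novel_haplotypes == {}

    def test_founder_draws_follow_the_weighted_distribution(self, pool):
        ids, weights = founder_weights(pool)
        rng = np.random.default_rng(8)
        n = 10_000
        draws = rng.choice(ids, size=n, p=weights)
        counts = {i: 0 for i in ids}
        for d in draws:
            counts[str(d)] += 1
        for i, w in zip(ids, weights):
            se = (w * (1 - w) / n) ** 0.5
            assert abs(counts[i] / n - w) <= 3 * se + 1e-9, i

    def test_zero_count_haplotypes_get_weight_one(self, pool):
        ids, weights = founder_weights(pool)
        w = dict(zip(ids, weights))
        total = sum(pool.get(i).original_count or 1 for i in ids)
        assert w["29"] == pytest.approx(1 / total)  # original count 1
        # BPRC count is 0 for 22/29/32 but original weights are used
        assert w["22"] == pytest.approx(2 / total)

    def test_matrilines_propagate_through_dams(self):
        truth, _ = simulate_colony(
            SimConfig(n_founders=8, n_generations=4, seed=6)
        )
        for rec in truth.pedigree:
            if rec.dam_id is not None:
                assert rec.matriline == truth.pedigree.get(rec.dam_id).matriline


class TestObservations:
    def test_zero_dropout_equals_noiseless_union(self):
        cfg = SimConfig(n_founders=8, n_generations=3, seed=4,
                        dropout_rate_per_locus=0.0, str_dropout_rate=0.0)
        truth, records = simulate_colony(cfg)
        for aid, rec in records.items():
            clean = genotype_from_diplotype(
                truth.diplotypes[aid], truth.working_pool, aid
            )
            assert rec.locus_alleles == clean.locus_alleles
            assert rec.str_profile == clean.str_profile
            assert rec.missing == clean.missing

    def test_full_dropout_retains_records_with_everything_missing(self):
        cfg = SimConfig(n_founders=8, n_generations=3, seed=4,
                        dropout_rate_per_locus=1.0, str_dropout_rate=1.0)
        truth, records = simulate_colony(cfg)
        assert set(records) == set(truth.diplotypes)
        for rec in records.values():
            assert not rec.locus_alleles and not rec.str_profile
            assert rec.missing

    def test_dropout_fraction_matches_binomial_expectation(self):
        cfg = SimConfig(n_founders=26, n_generations=3, seed=4,
                        recomb_rate_per_meiosis=0.0,
                        dropout_rate_per_locus=0.1, str_dropout_rate=0.0)
        truth, records = simulate_colony(cfg)
        total = missing = 0
        for aid, rec in records.items():
            clean = genotype_from_diplotype(
                truth.diplotypes[aid], truth.working_pool, aid
            )
            observable = set(clean.locus_alleles)
            total += len(observable)
            missing += len(observable & rec.missing)
        p = 0.1
        se = (p * (1 - p) / total) ** 0.5
        assert total > 500
        assert abs(missing / total - p) <= 3 * se


class TestEndToEnd:
    def test_clean_colonies_phase_back_to_truth(self):
        from mhckit.phasing import phase_pedigree

        wrong = 0
        rates = []
        for seed in range(5):
            cfg = SimConfig(n_founders=12, n_generations=4,
                            recomb_rate_per_meiosis=0.0,
                            dropout_rate_per_locus=0.0, str_dropout_rate=0.0,
                            seed=seed)
            truth, records = simulate_colony(cfg)
            cohort = phase_pedigree(records, truth.pedigree, truth.working_pool)
            for aid, phase in cohort.animals.items():
                if phase.status == "resolved":
                    if phase.diplotype.pair != truth.diplotypes[aid].pair:
                        wrong += 1
            rates.append(cohort.resolution_rate())
        assert wrong == 0
        assert min(rates) >= 0.95
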