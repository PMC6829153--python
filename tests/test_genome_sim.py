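"""Genome-wide individual-based simulator at miniature scale."""

import numpy as np
import pytest

from sexantag import _kernels
from sexantag.genome_sim import (
    GenomeSimConfig,
    LocusEffects,
    draw_effects,
    individual_fitness,
    new_mutations,
    recombine,
    recombine_with_breakpoints,
    run_genome_sim,
)


class TestEffectDraws:
    def test_antagonistic_signs_opposed(self, rng):
        cfg = GenomeSimConfig()
        eff = draw_effects(2000, cfg, rng)
        assert (np.sign(eff.s_f) == -np.sign(eff.s_m)).all()
        assert (np.abs(eff.s_f) > 0).all()
        # both orientations occur, roughly evenly
        frac_female = (eff.s_f > 0).mean()
        assert 0.4 < frac_female < 0.6

    def test_effect_magnitudes_half_gaussian(self, rng):
        cfg = GenomeSimConfig(effect_sd=0.01)
        eff = draw_effects(20_000, cfg, rng)
        # E|N(0, sd)| = sd * sqrt(2/pi)
        assert np.abs(eff.s_f).mean() == pytest.approx(
            0.01 * np.sqrt(2 / np.pi), rel=0.05
        )

    def test_neutral_forces_zero_effects(self, rng):
        cfg = GenomeSimConfig(neutral=True)
        eff = draw_effects(100, cfg, rng)
        assert (eff.s_f == 0).all() and (eff.s_m == 0).all()
        assert ((eff.h_f >= 0) & (eff.h_f <= 1)).all()

    def test_dominance_uniform(self, rng):
        eff = draw_effects(20_000, GenomeSimConfig(), rng)
        assert eff.h_f.mean() == pytest.approx(0.5, abs=0.02)
        assert eff.h_m.std() == pytest.approx(np.sqrt(1 / 12), rel=0.05)


class TestNewMutations:
    def test_zero_rate_leaves_haplotype(self, rng):
        cfg = GenomeSimConfig(mutation_rate=0.0)
        hap = np.array([1, 0, 1], dtype=np.uint8)
        loci = draw_effects(3, cfg, rng)
        out, loci2 = new_mutations(hap, loci, cfg, rng)
        np.testing.assert_array_equal(out, hap)
        assert len(loci2) == 3

    def test_expected_count_per_gamete(self, rng):
        # mu * G = 1e-10 * 1e8 = 0.01 expected new mutations per gamete
        cfg = GenomeSimConfig()
        n = sum(
            len(new_mutations(np.empty(0, np.uint8),
                              LocusEffects.empty(), cfg, rng)[1])
            for _ in range(20_000)
        )
        assert n == pytest.approx(200, rel=0.3)

    def test_new_sites_sorted_and_carried(self, rng):
        cfg = GenomeSimConfig(mutation_rate=1e-7)  # ~10 new per gamete
        loci = draw_effects(5, cfg, rng)
        order = np.argsort(loci.position)
        loci = loci.take(order)
        hap = np.zeros(5, dtype=np.uint8)
        out, loci2 = new_mutations(hap, loci, cfg, rng)
        assert (np.diff(loci2.position) > 0).all()
        assert out.sum() == len(loci2) - 5


class TestRecombine:
    def test_no_crossovers_copies_one_parent(self, rng):
        cfg = GenomeSimConfig(recombination_rate=0.0)
        pos = np.sort(rng.uniform(0, cfg.genome_length, 20))
        a = rng.integers(0, 2, 20).astype(np.uint8)
        b = rng.integers(0, 2, 20).astype(np.uint8)
        picks = {0: 0, 1: 0}
        for _ in range(40):
            g = recombine(a, b, pos, cfg, rng)
            if np.array_equal(g, a):
                picks[0] += 1
            elif np.array_equal(g, b):
                picks[1] += 1
        assert picks[0] + picks[1] == 40
        assert picks[0] > 5 and picks[1] > 5  # fair starting haplotype

    def test_empty_haplotypes_give_empty_gamete(self, rng):
        cfg = GenomeSimConfig()
        g = recombine(
            np.empty(0, np.uint8), np.empty(0, np.uint8), np.empty(0),
            cfg, rng,
        )
        assert g.size == 0

    def test_breakpoint_segments_alternate(self):
        pos = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        a = np.zeros(5, dtype=np.uint8)
        b = np.ones(5, dtype=np.uint8)
        out = recombine_with_breakpoints(a, b, pos, np.array([25.0]), start=0)
        np.testing.assert_array_equal(out, [0, 0, 1, 1, 1])
        out = recombine_with_breakpoints(
            a, b, pos, np.array([15.0, 45.0]), start=1
        )
        np.testing.assert_array_equal(out, [1, 0, 0, 0, 1])

    def test_kernel_matches_reference_implementation(self, rng):
        """The batched transmission kernel and the reference single-gamete
        path agree for identical breakpoints."""
        n_loci = 50
        pos = np.sort(rng.uniform(0, 1e6, n_loci))
        hap = rng.integers(0, 2, (2, n_loci)).astype(np.uint8)
        for n_bp in (0, 1, 2, 5):
            bps = np.sort(rng.uniform(0, 1e6, n_bp))
            for start in (0, 1):
                ref = recombine_with_breakpoints(
                    hap[0], hap[1], pos, bps, start
                )
                out = np.zeros((1, n_loci), dtype=np.uint8)
                _kernels.transmit(
                    hap, pos, np.array([0], dtype=np.int64),
                    np.array([start], dtype=np.uint8),
                    bps, np.array([0, n_bp], dtype=np.int64), out,
                )
                np.testing.assert_array_equal(out[0], ref)

    def test_expected_crossover_count_is_one(self, rng):
        cfg = GenomeSimConfig()
        assert cfg.recombination_rate * cfg.genome_length == pytest.approx(1.0)


class TestIndividualFitness:
    def test_mutation_free_individual(self):
        assert individual_fitness(
            np.empty(0, np.uint8), np.empty(0), np.empty(0)
        ) == 1.0

    def test_beneficial_heterozygote_clamped(self):
        w = individual_fitness(
            np.array([1]), np.array([0.01]), np.array([0.5])
        )
        assert w == 1.0  # 1.005 exceeds the survival-probability cap

    def test_deleterious_homozygote(self):
        w = individual_fitness(
            np.array([2]), np.array([-0.02]), np.array([0.3])
        )
        assert w == pytest.approx(0.98)

    def test_multiplicative_across_loci(self):
        s = np.array([-0.1, -0.2])
        h = np.array([0.5, 1.0])
        w = individual_fitness(np.array([1, 2]), s, h)
        assert w == pytest.approx(0.95 * 0.8)

    def test_fitness_kernel_matches_direct_product(self, rng):
        n_loci = 30
        loci = draw_effects(n_loci, GenomeSimConfig(), rng)
        hap = rng.integers(0, 2, (4, n_loci)).astype(np.uint8)
        sex = np.array([0, 1], dtype=np.uint8)
        out = np.zeros(2)
        _kernels.log_fitness(
            hap, 0, 2, sex,
            np.log1p(loci.h_f * loci.s_f), np.log1p(loci.s_f),
            np.log1p(loci.h_m * loci.s_m), np.log1p(loci.s_m), out,
        )
        for i, (s, h) in enumerate(
            [(loci.s_f, loci.h_f), (loci.s_m, loci.h_m)]
        ):
            g = hap[2 * i] + hap[2 * i + 1]
            w = np.prod(np.where(g == 1, 1 + h * s, np.where(g == 2, 1 + s, 1.0)))
            assert np.exp(out[i]) == pytest.approx(w, rel=1e-12)


class TestMiniatureRuns:
    def test_census_regulated(self, mini_antagonistic_population):
        census = mini_antagonistic_population.census
        assert census.min() > 0.8 * 300
        assert census.max() < 1.25 * 300

    def test_neutral_run_has_zero_load(self, mini_neutral_population):
        assert mini_neutral_population.load == 0.0

    def test_segregating_sites_accumulate(self, mini_neutral_population):
        assert mini_neutral_population.n_segregating > 5
        table = mini_neutral_population.per_locus
        freq = table["freq_total"].to_numpy()
        assert ((freq > 0) & (freq < 1)).all()

    def test_per_locus_table_consistency(self, mini_antagonistic_population):
        rep = mini_antagonistic_population
        table = rep.per_locus
        pop = rep.population
        assert len(table) == len(pop.loci)
        n_f = (pop.sex == 0).sum()
        n_m = (pop.sex == 1).sum()
        recomputed = (
            table.count_f + table.count_m
        ) / (2.0 * (n_f + n_m))
        np.testing.assert_allclose(table.freq_total, recomputed, atol=1e-12)
        assert (np.diff(table.position) > 0).all()

    def test_seed_determinism(self):
        cfg = GenomeSimConfig(
            carrying_capacity=100, genome_length=1e6, mutation_rate=1e-7,
            steps=20, replicates=2, seed=42,
        )
        a = run_genome_sim(cfg)
        b = run_genome_sim(cfg)
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(
                ra.population.haplotypes, rb.population.haplotypes
            )
            np.testing.assert_array_equal(ra.census, rb.census)
        # replicates use distinct child seeds
        assert not np.array_equal(
            a.replicates[0].census, a.replicates[1].census
        )

    def test_antagonistic_load_positive(self, mini_antagonistic_population):
        # at the scaled-up mutation supply of the miniature scenario some
        # balanced polymorphisms exist, so load is measurably positive
        assert mini_antagonistic_population.load > 0.0
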