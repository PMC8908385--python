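"""Forward simulator: frequency hierarchy, gamete union, tetrad rule."""

import numpy as np
import pytest

from mixopop.simulate import (
    InvalidConfigError,
    SimConfig,
    SporophyteGenotype,
    blade_from_sporophyte,
    draw_frequency_set,
    make_sporophyte,
    simulate_dataset,
)


def small_config(**kw):
    base = dict(
        n_species=1,
        clusters_per_species=2,
        pops_per_cluster=2,
        inds_per_pop=5,
        n_loci=4,
        alleles_per_locus=4,
        species_divergence=0.0,
        hybrid_fraction=0.0,
        dropout_prob=0.0,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("fct_sim", 1.0),
            ("fsc_sim", -0.1),
            ("dropout_prob", 1.5),
            ("n_loci", 0),
            ("ploidy_weights", (0.5, 0.5, 0.5)),
        ],
    )
    def test_invalid_configs_rejected(self, field, value):
        with pytest.raises(InvalidConfigError):
            small_config(**{field: value}).validate()

    def test_allele_size_grid(self):
        cfg = small_config(alleles_per_locus=3, repeat_unit=3, allele_offset=100)
        assert list(cfg.allele_sizes) == [100, 103, 106]


class TestFrequencySet:
    def test_zero_drift_copies_ancestor(self):
        cfg = small_config(fct_sim=0.0, fsc_sim=0.0)
        fs = draw_frequency_set(cfg)
        for locus in range(cfg.n_loci):
            anc = fs.freqs[(0, -1, -1, locus)]
            for c in range(2):
                for p in range(2):
                    np.testing.assert_array_equal(fs.freqs[(0, c, p, locus)], anc)

    def test_monomorphic_locus(self):
        cfg = small_config(alleles_per_locus=1, fct_sim=0.2, fsc_sim=0.1)
        fs = draw_frequency_set(cfg)
        for key, vec in fs.freqs.items():
            np.testing.assert_allclose(vec, [1.0])

    def test_vectors_are_probabilities(self):
        fs = draw_frequency_set(small_config(fct_sim=0.2, fsc_sim=0.1))
        for vec in fs.freqs.values():
            assert np.all(vec >= 0)
            assert abs(vec.sum() - 1.0) < 1e-9

    def test_balding_nichols_f_recovered(self):
        # mean Wright-style F among cluster vectors ~ fct_sim, by the direct
        # variance-of-p estimator var(p) / (pbar (1 - pbar))
        cfg = small_config(
            clusters_per_species=8, pops_per_cluster=1, n_loci=50, fct_sim=0.25, seed=3
        )
        fs = draw_frequency_set(cfg)
        ratios = []
        for locus in range(cfg.n_loci):
            mats = np.array([fs.freqs[(0, c, -1, locus)] for c in range(8)])
            pbar = mats.mean(axis=0)
            var = mats.var(axis=0)
            keep = (pbar > 0.05) & (pbar < 0.95)
            if keep.any():
                ratios.append(np.mean(var[keep] / (pbar[keep] * (1 - pbar[keep]))))
        assert abs(np.mean(ratios) - 0.25) < 0.03


class TestSporophyte:
    def test_fixed_population_gives_homozygote(self):
        rng = np.random.default_rng(0)
        sizes = np.array([100])
        sporo = make_sporophyte([np.array([1.0])] * 3, sizes, 4, rng)
        assert sporo.alleles == [(100, 100, 100, 100)] * 3

    @pytest.mark.parametrize("ploidy", [2, 4, 8])
    def test_multiset_size_equals_ploidy(self, ploidy):
        rng = np.random.default_rng(1)
        sizes = np.array([100, 103, 106])
        freqs = [np.array([0.5, 0.3, 0.2])] * 2
        sporo = make_sporophyte(freqs, sizes, ploidy, rng)
        assert all(len(a) == ploidy for a in sporo.alleles)

    def test_invalid_ploidy_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            make_sporophyte([np.array([1.0])], np.array([100]), 3, rng)

    def test_heterozygote_fraction_binomial(self):
        rng = np.random.default_rng(42)
        sizes = np.array([100, 103])
        freqs = [np.array([0.5, 0.5])]
        het = sum(
            len(set(make_sporophyte(freqs, sizes, 2, rng).alleles[0])) == 2
            for _ in range(10_000)
        )
        assert abs(het / 10_000 - 0.5) < 0.02


class TestBladeUnion:
    def test_diploid_union_is_parental_set(self):
        rng = np.random.default_rng(0)
        sporo = SporophyteGenotype(ploidy=2, alleles=[(100, 103)])
        assert blade_from_sporophyte(sporo, 0.0, rng) == [frozenset({100, 103})]

    def test_distinct_set_rule_with_dosage(self):
        rng = np.random.default_rng(0)
        sporo = SporophyteGenotype(ploidy=4, alleles=[(100, 100, 103, 106)])
        assert blade_from_sporophyte(sporo, 0.0, rng) == [frozenset({100, 103, 106})]

    def test_octoploid_six_distinct_alleles(self):
        rng = np.random.default_rng(0)
        sporo = SporophyteGenotype(
            ploidy=8, alleles=[(100, 100, 103, 103, 106, 109, 112, 115)]
        )
        (obs,) = blade_from_sporophyte(sporo, 0.0, rng)
        assert len(obs) == 6

    def test_full_dropout_marks_missing(self):
        rng = np.random.default_rng(0)
        sporo = SporophyteGenotype(ploidy=2, alleles=[(100, 103)])
        assert blade_from_sporophyte(sporo, 1.0, rng) == [None]


class TestSimulateDataset:
    def test_individual_count_bookkeeping(self):
        cfg = SimConfig(
            n_species=2, clusters_per_species=2, pops_per_cluster=3, inds_per_pop=20,
            n_loci=2, seed=0,
        )
        sim = simulate_dataset(cfg)
        assert len(sim.individuals) == 240

    def test_determinism_under_fixed_seed(self):
        cfg = small_config(dropout_prob=0.1, seed=9)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        for x, y in zip(a.individuals, b.individuals):
            assert x.observed == y.observed
            assert x.cp_sequence == y.cp_sequence
            assert x.ploidy == y.ploidy

    def test_all_diploid_never_exceeds_two_alleles(self):
        cfg = small_config(ploidy_weights=(1.0, 0.0, 0.0), inds_per_pop=30)
        sim = simulate_dataset(cfg)
        for ind in sim.individuals:
            assert ind.ploidy == 2
            for obs in ind.observed:
                assert obs is None or len(obs) <= 2

    def test_union_bound_per_ploidy(self):
        sim = simulate_dataset(small_config(inds_per_pop=30, ploidy_weights=(0.3, 0.3, 0.4)))
        for ind in sim.individuals:
            for obs in ind.observed:
                assert obs is None or len(obs) <= ind.ploidy

    def test_no_hybrids_means_native_cp_pool(self):
        cfg = SimConfig(
            n_species=2, clusters_per_species=1, pops_per_cluster=2, inds_per_pop=10,
            n_loci=2, hybrid_fraction=0.0, cp_seq_length=60, seed=4,
        )
        sim = simulate_dataset(cfg)
        for ind in sim.individuals:
            assert ind.cp_haplotype_id.startswith(ind.species_label)

    def test_cp_sequences_have_configured_length(self):
        sim = simulate_dataset(small_config(cp_seq_length=80))
        assert {len(ind.cp_sequence) for ind in sim.individuals} == {80}

    def test_frequency_recovery_by_naive_counting(self):
        # large diploid population: allele counting recovers the truth
        cfg = small_config(
            clusters_per_species=1, pops_per_cluster=1, inds_per_pop=2000,
            n_loci=2, fct_sim=0.0, fsc_sim=0.0, ploidy_weights=(1.0, 0.0, 0.0), seed=2,
        )
        sim = simulate_dataset(cfg)
        sizes = cfg.allele_sizes
        for locus in range(cfg.n_loci):
            counts = np.zeros(len(sizes))
            n = 0
            for ind in sim.individuals:
                obs = ind.observed[locus]
                assert obs is not None
                # diploid with dropout 0: 1 allele = homozygote (2 copies)
                if len(obs) == 1:
                    counts[list(sizes).index(next(iter(obs)))] += 2
                else:
                    for a in obs:
                        counts[list(sizes).index(a)] += 1
                n += 2
            est = counts / n
            truth = sim.truth.freqs[(0, 0, 0, locus)]
            assert np.max(np.abs(est - truth)) < 0.02
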