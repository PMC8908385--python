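"""Diversity, differentiation, AMOVA (with naive oracle) and PCA."""

import numpy as np
import pandas as pd
import pytest

from mixopop.dataio import dataset_from_simulation
from mixopop.ploidy import recode_dataset
from mixopop.popstats import (
    Hierarchy,
    amova,
    diversity_table,
    effective_alleles,
    gene_diversity,
    pairwise_differentiation,
    pca_genotypes,
    population_frequencies,
)
from mixopop.simulate import SimConfig, simulate_dataset

from conftest import make_dataset, naive_amova_components


class TestGeneDiversity:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.25] * 4, 0.75)],
    )
    def test_closed_form(self, freqs, expected):
        assert gene_diversity(freqs) == pytest.approx(expected)

    @pytest.mark.parametrize("hs,expected", [(0.0, 1.0), (0.5, 2.0), (0.75, 4.0)])
    def test_effective_alleles(self, hs, expected):
        assert effective_alleles(hs) == pytest.approx(expected)

    def test_effective_alleles_domain(self):
        with pytest.raises(ValueError):
            effective_alleles(1.0)

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValueError):
            gene_diversity([0.5, 0.4])


class TestDiversityTable:
    def test_monomorphic_population(self):
        ds = make_dataset(
            {f"I{i}": ("P1", "S", {"L1": {100}, "L2": {103}}) for i in range(4)}
        )
        for m in (2, 4, 8):
            coding = recode_dataset(ds, m, seed=0)
            table = diversity_table(ds, coding)
            assert table.loc[0, "Hs"] == pytest.approx(0.0)
            assert table.loc[0, "EN"] == pytest.approx(1.0)

    def test_en_hs_bijection(self):
        cfg = SimConfig(
            n_species=1, clusters_per_species=1, pops_per_cluster=3, inds_per_pop=15,
            n_loci=5, fsc_sim=0.05, fct_sim=0.0, species_divergence=0.0,
            hybrid_fraction=0.0, seed=2,
        )
        ds, _ = dataset_from_simulation(simulate_dataset(cfg))
        table = diversity_table(ds, recode_dataset(ds, 4, seed=0))
        for _, row in table.iterrows():
            assert row["EN"] == pytest.approx(1.0 / (1.0 - row["Hs"]), abs=1e-9)

    def test_diversity_ordering_preserved_across_ploidies(self):
        # a high-diversity and a low-diversity pool keep their EN order at
        # every assumed ploidy
        high = SimConfig(
            n_species=1, clusters_per_species=1, pops_per_cluster=2, inds_per_pop=30,
            n_loci=6, alleles_per_locus=8, fsc_sim=0.02, fct_sim=0.0,
            species_divergence=0.0, hybrid_fraction=0.0, seed=3,
        )
        low = high.replace(alleles_per_locus=2, seed=4)
        ds_h, _ = dataset_from_simulation(simulate_dataset(high))
        ds_l, _ = dataset_from_simulation(simulate_dataset(low))
        for m in (2, 4, 8):
            en_h = diversity_table(ds_h, recode_dataset(ds_h, m, seed=0))["EN"].mean()
            en_l = diversity_table(ds_l, recode_dataset(ds_l, m, seed=0))["EN"].mean()
            assert en_h > en_l

    def test_hs_shift_across_ploidies_bounded_and_monotone(self):
        # coding diploid-truth data at a higher assumed ploidy deflates Hs
        # mildly and systematically (the polyploid HWE fit must skew
        # frequencies to explain the excess of one-allele phenotypes); the
        # shift stays bounded and ordered, never erratic
        cfg = SimConfig(
            n_species=1, clusters_per_species=1, pops_per_cluster=2, inds_per_pop=40,
            n_loci=8, fsc_sim=0.02, fct_sim=0.0, species_divergence=0.0,
            ploidy_weights=(1.0, 0.0, 0.0), dropout_prob=0.0, hybrid_fraction=0.0,
            seed=5,
        )
        ds, _ = dataset_from_simulation(simulate_dataset(cfg))
        hs = {
            m: diversity_table(ds, recode_dataset(ds, m, seed=0))["Hs"].mean()
            for m in (2, 4, 8)
        }
        assert hs[2] >= hs[4] - 1e-6 >= hs[8] - 2e-6
        assert max(abs(hs[a] - hs[b]) for a in hs for b in hs) < 0.15


def _freqs_from_vectors(vectors):
    """Build the population_frequencies return shape from plain vectors:
    {pop: {locus: {allele: prob}}}."""
    from mixopop.ploidy import AlleleFrequencyEstimate

    out = {}
    for pop, loci in vectors.items():
        out[pop] = {}
        for locus, dist in loci.items():
            alleles = tuple(sorted(dist))
            probs = np.array([dist[a] for a in alleles])
            out[pop][locus] = AlleleFrequencyEstimate(
                alleles=alleles, probs=probs, log_likelihood=0.0,
                n_iterations=0, converged=True, n_phenotypes=1,
            )
    return out


class TestPairwiseDifferentiation:
    def test_identical_populations_zero(self):
        freqs = _freqs_from_vectors(
            {
                "A": {"L1": {1: 0.5, 2: 0.5}},
                "B": {"L1": {1: 0.5, 2: 0.5}},
            }
        )
        for stat in ("Gst", "JostD"):
            mat = pairwise_differentiation(freqs, stat).values
            assert mat.loc["A", "B"] == pytest.approx(0.0)
            assert mat.loc["A", "A"] == 0.0

    def test_fixed_difference_is_one(self):
        freqs = _freqs_from_vectors(
            {"A": {"L1": {1: 1.0}}, "B": {"L1": {2: 1.0}}}
        )
        for stat in ("Gst", "JostD"):
            mat = pairwise_differentiation(freqs, stat).values
            assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_shared_monomorphism_defined_zero(self):
        freqs = _freqs_from_vectors({"A": {"L1": {1: 1.0}}, "B": {"L1": {1: 1.0}}})
        mat = pairwise_differentiation(freqs, "Gst").values
        assert mat.loc["A", "B"] == 0.0

    def test_matrix_symmetric_zero_diagonal(self):
        freqs = _freqs_from_vectors(
            {
                "A": {"L1": {1: 0.9, 2: 0.1}},
                "B": {"L1": {1: 0.5, 2: 0.5}},
                "C": {"L1": {1: 0.2, 2: 0.8}},
            }
        )
        mat = pairwise_differentiation(freqs, "Gst").values
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0.0)

    def test_between_cluster_exceeds_within_cluster(self):
        cfg = SimConfig(
            n_species=1, clusters_per_species=2, pops_per_cluster=3, inds_per_pop=20,
            n_loci=8, fct_sim=0.20, fsc_sim=0.03, species_divergence=0.0,
            hybrid_fraction=0.0, seed=6,
        )
        ds, meta = dataset_from_simulation(simulate_dataset(cfg))
        coding = recode_dataset(ds, 2, seed=0)
        freqs = population_frequencies(ds, coding)
        mat = pairwise_differentiation(freqs, "Gst").values
        cluster_of = {p.population_code: p.cluster_label for p in meta}
        within, between = [], []
        pops = list(mat.index)
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                (within if cluster_of[a] == cluster_of[b] else between).append(
                    mat.loc[a, b]
                )
        assert np.mean(between) > np.mean(within)


class TestAmova:
    def test_degenerate_fixed_partition(self, two_group_fixed_dataset):
        ds = two_group_fixed_dataset
        coding = recode_dataset(ds, 2, seed=0)
        h = Hierarchy({f"G{g}P{p}": f"G{g}" for g in range(2) for p in range(2)})
        res = amova(ds, coding, h, replicates=2, seed=0)
        assert res.f_stats["F_CT"] == pytest.approx(1.0)
        assert res.f_stats["F_SC"] == pytest.approx(0.0)
        assert res.pct_variance["among_groups"] == pytest.approx(100.0)

    def test_zero_variance_flags_nan(self):
        ds = make_dataset(
            {
                f"I{i}": (f"P{i % 4}", "S", {"L1": {100}})
                for i in range(12)
            }
        )
        coding = recode_dataset(ds, 2, seed=0)
        h = Hierarchy({f"P{p}": f"G{p % 2}" for p in range(4)})
        with pytest.warns(UserWarning, match="zero"):
            res = amova(ds, coding, h, replicates=2, seed=0)
        assert np.isnan(res.f_stats["F_CT"])

    def test_single_population_group_rejected(self):
        ds = make_dataset(
            {f"I{i}": (f"P{i % 3}", "S", {"L1": {100, 103}}) for i in range(9)}
        )
        coding = recode_dataset(ds, 2, seed=0)
        h = Hierarchy({"P0": "G0", "P1": "G0", "P2": "G1"})
        with pytest.raises(ValueError, match="single population"):
            amova(ds, coding, h, replicates=1, seed=0)

    def test_pct_variance_sums_to_100(self):
        cfg = SimConfig(
            n_species=1, clusters_per_species=2, pops_per_cluster=2, inds_per_pop=12,
            n_loci=4, fct_sim=0.15, fsc_sim=0.05, species_divergence=0.0,
            hybrid_fraction=0.0, seed=8,
        )
        ds, meta = dataset_from_simulation(simulate_dataset(cfg))
        h = Hierarchy({p.population_code: p.cluster_label for p in meta})
        for m in (2, 4):
            res = amova(ds, recode_dataset(ds, m, seed=0), h, replicates=3, seed=0)
            assert sum(res.pct_variance.values()) == pytest.approx(100.0, abs=1e-6)

    def test_oracle_equivalence_balanced_diploid(self):
        # unambiguous diploid data: components must match the brute-force
        # sums-of-squares oracle to 1e-9
        rng = np.random.default_rng(12)
        structure = {}
        cells = {}
        for g in range(2):
            structure[f"G{g}"] = {}
            for p in range(3):
                pop = f"G{g}P{p}"
                inds = []
                for i in range(4):
                    copies = tuple(sorted(rng.choice([100, 103, 106], size=2).tolist()))
                    inds.append(copies)
                    cells[f"{pop}I{i}"] = (pop, "S", {"L1": set(copies)})
                structure[f"G{g}"][pop] = inds
        ds = make_dataset(cells)
        coding = recode_dataset(ds, 2, seed=0)
        h = Hierarchy({f"G{g}P{p}": f"G{g}" for g in range(2) for p in range(3)})
        res = amova(ds, coding, h, replicates=1, seed=0)
        sa, sb, sc, sw = naive_amova_components(structure, m=2)
        assert res.sigma2["among_groups"] == pytest.approx(sa, abs=1e-9)
        assert res.sigma2["among_pops_within_groups"] == pytest.approx(sb, abs=1e-9)
        assert res.sigma2["among_individuals_within_pops"] == pytest.approx(sc, abs=1e-9)
        assert res.sigma2["within_individuals"] == pytest.approx(sw, abs=1e-9)

    def test_oracle_equivalence_unbalanced(self):
        # unequal pop sizes exercise the unequal-size coefficients
        rng = np.random.default_rng(21)
        structure = {}
        cells = {}
        sizes = {"G0P0": 3, "G0P1": 6, "G1P0": 4, "G1P1": 5}
        for pop, n in sizes.items():
            g = pop[:2]
            structure.setdefault(g, {})[pop] = []
            for i in range(n):
                copies = tuple(sorted(rng.choice([100, 103, 106, 109], size=2).tolist()))
                structure[g][pop].append(copies)
                cells[f"{pop}I{i}"] = (pop, "S", {"L1": set(copies)})
        ds = make_dataset(cells)
        coding = recode_dataset(ds, 2, seed=0)
        h = Hierarchy({pop: pop[:2] for pop in sizes})
        res = amova(ds, coding, h, replicates=1, seed=0)
        sa, sb, sc, sw = naive_amova_components(structure, m=2)
        for key, val in zip(
            ("among_groups", "among_pops_within_groups",
             "among_individuals_within_pops", "within_individuals"),
            (sa, sb, sc, sw),
        ):
            assert res.sigma2[key] == pytest.approx(val, abs=1e-9)

    def test_fct_recovery_from_simulation(self):
        cfg = SimConfig(
            n_species=1, clusters_per_species=4, pops_per_cluster=2, inds_per_pop=20,
            n_loci=10, fct_sim=0.25, fsc_sim=0.10, species_divergence=0.0,
            ploidy_weights=(1.0, 0.0, 0.0), dropout_prob=0.0, hybrid_fraction=0.0,
            seed=11,
        )
        ds, meta = dataset_from_simulation(simulate_dataset(cfg))
        h = Hierarchy({p.population_code: p.cluster_label for p in meta})
        res = amova(ds, recode_dataset(ds, 2, seed=0), h, replicates=3, seed=0)
        assert abs(res.f_stats["F_CT"] - 0.25) < 0.05
        assert abs(res.f_stats["F_SC"] - 0.10) < 0.03


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        cells = {}
        for i in range(5):
            cells[f"A{i}"] = ("PA", "S", {"L1": {100}, "L2": {130}})
            cells[f"B{i}"] = ("PB", "S", {"L1": {103}, "L2": {133}})
        ds = make_dataset(cells)
        res = pca_genotypes(ds, recode_dataset(ds, 2, seed=0))
        pc1 = res.coordinates["PC1"]
        a = pc1[[f"A{i}" for i in range(5)]]
        b = pc1[[f"B{i}" for i in range(5)]]
        assert (a.max() < b.min()) or (b.max() < a.min())
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self):
        cells = {
            f"I{i}": ("P1" if i % 2 else "P2", "S", {"L1": {100 + 3 * (i % 3)}})
            for i in range(8)
        }
        ds = make_dataset(cells)
        ds_rev = make_dataset(dict(reversed(list(cells.items()))))
        c1 = pca_genotypes(ds, recode_dataset(ds, 2, seed=0)).coordinates
        c2 = pca_genotypes(ds_rev, recode_dataset(ds_rev, 2, seed=0)).coordinates
        pd.testing.assert_frame_equal(c1.sort_index(), c2.sort_index())

    def test_species_recovered_by_clustering_pc1(self):
        from scipy.cluster.vq import kmeans2

        cfg = SimConfig(
            n_species=2, clusters_per_species=1, pops_per_cluster=2, inds_per_pop=30,
            n_loci=8, fct_sim=0.0, fsc_sim=0.05, species_divergence=0.3,
            hybrid_fraction=0.0, seed=13,
        )
        sim = simulate_dataset(cfg)
        ds, _ = dataset_from_simulation(sim)
        res = pca_genotypes(ds, recode_dataset(ds, 2, seed=0))
        pc1 = res.coordinates["PC1"].to_numpy()
        _, labels = kmeans2(pc1[:, None], 2, seed=1, minit="++")
        truth = np.array(
            [0 if ind.species_label == "SP1" else 1 for ind in sim.individuals]
        )
        agreement = max(np.mean(labels == truth), np.mean(labels != truth))
        assert agreement > 0.95

    def test_all_missing_individual_dropped(self):
        cells = {
            "I1": ("P1", "S", {"L1": {100}}),
            "I2": ("P1", "S", {"L1": {103}}),
            "I3": ("P1", "S", {"L1": None}),
        }
        ds = make_dataset(cells)
        with pytest.warns(UserWarning, match="dropped"):
            res = pca_genotypes(ds, recode_dataset(ds, 2, seed=0))
        assert "I3" not in res.coordinates.index
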