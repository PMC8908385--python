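import numpy as np
import pytest

from mixopop.dataio import GenotypeDataset, IndividualRecord


def make_dataset(cells, locus_names=None):
    """Build a GenotypeDataset from {individual_id: (pop, species, {locus: alleles})}.

    ``alleles`` may be a set/tuple of ints or None for missing.
    """
    loci = locus_names or sorted(
        {locus for _, _, locimap in cells.values() for locus in locimap}
    )
    individuals = [
        IndividualRecord(
            individual_id=ind_id,
            population=pop,
            species=species,
            loci={
                locus: (frozenset(locimap[locus]) if locimap.get(locus) else None)
                for locus in loci
            },
        )
        for ind_id, (pop, species, locimap) in cells.items()
    ]
    return GenotypeDataset(individuals=individuals, locus_names=list(loci))


def naive_amova_components(structure, m):
    """Brute-force AMOVA oracle on explicit allele copies.

    ``structure``: {group: {pop: [ind_copies, ...]}} where ``ind_copies`` is
    a length-m tuple of allele states per individual (single locus).
    Sums of squares are computed by direct O(n^2) loops over 0/1 pairwise
    distances; variance components by solving the expected-mean-square
    system numerically.  Returns (sigma_a, sigma_b, sigma_c, sigma_w).
    """

    def ss(alleles):
        n = len(alleles)
        if n == 0:
            return 0.0
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += 1.0 if alleles[i] != alleles[j] else 0.0
        return total / n

    all_alleles, group_sets, pop_sets, ind_sets = [], [], [], []
    n_p, n_g = [], []
    pop_group_index = []
    for gi, (_, pops) in enumerate(sorted(structure.items())):
        g_all = []
        for _, inds in sorted(pops.items()):
            p_all = []
            for copies in inds:
                ind_sets.append(list(copies))
                p_all.extend(copies)
            pop_sets.append(p_all)
            n_p.append(len(p_all))
            pop_group_index.append(gi)
            g_all.extend(p_all)
        group_sets.append(g_all)
        n_g.append(len(g_all))
        all_alleles.extend(g_all)

    N = len(all_alleles)
    I = len(ind_sets)
    P = len(pop_sets)
    G = len(group_sets)

    ss_total = ss(all_alleles)
    ss_wi = sum(ss(a) for a in ind_sets)
    ss_wp = sum(ss(a) for a in pop_sets)
    ss_wg = sum(ss(a) for a in group_sets)

    SS = np.array([ss_total - ss_wg, ss_wg - ss_wp, ss_wp - ss_wi, ss_wi])
    df = np.array([G - 1, P - G, I - P, N - I], dtype=float)
    MS = SS / df

    n_p = np.array(n_p, dtype=float)
    n_g = np.array(n_g, dtype=float)
    pop_group_index = np.array(pop_group_index)
    sum_np2_over_ng = sum(
        np.sum(n_p[pop_group_index == gi] ** 2) / n_g[gi] for gi in range(G)
    )
    k3 = (N - sum_np2_over_ng) / (P - G)
    k5 = (sum_np2_over_ng - np.sum(n_p**2) / N) / (G - 1)
    k6 = (N - np.sum(n_g**2) / N) / (G - 1)

    # expected mean squares, rows ordered AG, AP, AI, WI; unknowns a, b, c, w
    ems = np.array(
        [
            [k6, k5, m, 1.0],
            [0.0, k3, m, 1.0],
            [0.0, 0.0, m, 1.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return tuple(np.linalg.solve(ems, MS))


@pytest.fixture
def two_group_fixed_dataset():
    """2 groups x 2 pops x 5 diploid individuals; every pop fixed for its
    group's allele, groups fixed differently."""
    cells = {}
    for g in range(2):
        for p in range(2):
            for i in range(5):
                cells[f"G{g}P{p}I{i}"] = (f"G{g}P{p}", "X", {"L1": {100 + 3 * g}})
    return make_dataset(cells)
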