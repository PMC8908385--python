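"""Forward simulator of chimeric, mixoploid blade genotypes with known truth.

In bladed Bangiaceae the gametophytic thallus develops from the four meiotic
products of a single conchospore, so one blade carries up to four haploid
genotypes; blades may additionally be diploid or tetraploid chimeras
(mixoploids).  A microsatellite genotype of such a blade is therefore the
*union* of the distinct alleles carried by the sporophyte that produced the
tetrad: a diploid sporophyte can show up to 2 alleles per locus, a
tetraploid up to 4, an octoploid up to 8.

The simulator draws hierarchically structured allele frequencies
(species -> regional cluster -> population) from a nested Balding-Nichols
model so that the differentiation parameters ``fct_sim`` (among clusters)
and ``fsc_sim`` (among populations within clusters) are recoverable by a
hierarchical AMOVA, builds sporophytes of ploidy 2/4/8 by random union of
gametes, reduces them to observed allele sets via the tetrad-union rule,
and attaches maternally inherited cpDNA haplotypes with optional
interspecific introgression.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "FrequencySet",
    "SporophyteGenotype",
    "SimIndividual",
    "SimDataset",
    "draw_frequency_set",
    "make_sporophyte",
    "blade_from_sporophyte",
    "simulate_dataset",
]

# sub-stream tags so frequency draws, individuals and cpDNA evolve on
# independent reproducible streams derived from one user seed
_STREAM_FREQS = 1
_STREAM_INDS = 2
_STREAM_CP = 3


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the forward simulation.

    Defaults emulate the study conditions this package targets: two species
    gene pools, two regional clusters per species (a diverse "south" and a
    recolonised "north"), 440 blades genotyped at 10 microsatellite loci,
    mixed sporophyte ploidies, occasional interspecific hybrids and
    maternally inherited cpDNA with rare introgression.
    """

    n_species: int = 2
    clusters_per_species: int = 2
    pops_per_cluster: int = 5
    inds_per_pop: int = 22
    n_loci: int = 10
    alleles_per_locus: int = 8
    repeat_unit: int = 3
    allele_offset: int = 100
    fct_sim: float = 0.10
    fsc_sim: float = 0.07
    species_divergence: float = 0.30
    ploidy_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    selfing_rate: float = 0.1
    hybrid_fraction: float = 0.02
    introgression_prob: float = 0.5
    dropout_prob: float = 0.05
    cp_seq_length: int = 1141
    cp_haps_per_pool: int = 3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "clusters_per_species": self.clusters_per_species,
            "pops_per_cluster": self.pops_per_cluster,
            "inds_per_pop": self.inds_per_pop,
            "n_loci": self.n_loci,
            "alleles_per_locus": self.alleles_per_locus,
            "repeat_unit": self.repeat_unit,
            "cp_seq_length": self.cp_seq_length,
            "cp_haps_per_pool": self.cp_haps_per_pool,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise InvalidConfigError(f"{name} must be an integer >= 1, got {value!r}")
        for name in ("fct_sim", "fsc_sim", "species_divergence"):
            value = getattr(self, name)
            if not (0.0 <= value < 1.0) or not math.isfinite(value):
                raise InvalidConfigError(f"{name} must lie in [0, 1), got {value!r}")
        probs = {
            "selfing_rate": self.selfing_rate,
            "hybrid_fraction": self.hybrid_fraction,
            "introgression_prob": self.introgression_prob,
            "dropout_prob": self.dropout_prob,
        }
        for name, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {value!r}")
        w = np.asarray(self.ploidy_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise InvalidConfigError(
                "ploidy_weights must be 3 non-negative weights over ploidies "
                f"(2, 4, 8) summing to 1, got {self.ploidy_weights!r}"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def allele_sizes(self) -> np.ndarray:
        """Allele size grid: offset + k * repeat_unit, k = 0..A-1."""
        return self.allele_offset + self.repeat_unit * np.arange(self.alleles_per_locus)

    @property
    def n_individuals(self) -> int:
        return (
            self.n_species
            * self.clusters_per_species
            * self.pops_per_cluster
            * self.inds_per_pop
        )


@dataclass
class FrequencySet:
    """Truth allele frequencies, keyed (species, cluster, population, locus).

    ``freqs[(s, c, p, l)]`` is a probability vector aligned with
    ``allele_sizes``; species- and cluster-level ancestral vectors are kept
    for diagnostics under keys with population (and cluster) set to -1.
    """

    allele_sizes: np.ndarray
    freqs: dict[tuple[int, int, int, int], np.ndarray] = field(default_factory=dict)

    def population_vector(self, species: int, cluster: int, pop: int, locus: int) -> np.ndarray:
        return self.freqs[(species, cluster, pop, locus)]


@dataclass
class SporophyteGenotype:
    """A sporophyte of ploidy 2, 4 or 8: per locus a multiset of allele sizes."""

    ploidy: int
    alleles: list[tuple[int, ...]]  # per locus, sorted, length == ploidy

    def __post_init__(self) -> None:
        for locus, a in enumerate(self.alleles):
            if len(a) != self.ploidy:
                raise ValueError(
                    f"locus {locus}: {len(a)} allele copies, expected ploidy {self.ploidy}"
                )


@dataclass
class SimIndividual:
    individual_id: str
    population_code: str
    cluster_code: str
    species_label: str
    ploidy: int
    hybrid: bool
    observed: list[frozenset[int] | None]  # per locus; None = missing
    cp_haplotype_id: str
    cp_sequence: str


@dataclass
class SimDataset:
    config: SimConfig
    truth: FrequencySet
    locus_names: list[str]
    individuals: list[SimIndividual]

    @property
    def population_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population_code, None)
        return list(seen)


def _dirichlet_from_parent(parent: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols daughter vector: Dirichlet(parent * (1-f)/f).

    f = 0 copies the parent exactly (zero drift).  Zero entries in the
    parent stay zero (gamma with shape 0 is the point mass at 0).
    """
    if f == 0.0:
        return parent.copy()
    alpha = parent * (1.0 - f) / f
    if not np.all(np.isfinite(alpha)):
        raise InvalidConfigError("non-finite Dirichlet parameter; is f == 1?")
    draws = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-300)), 0.0)
    total = draws.sum()
    if total == 0.0:  # numerically degenerate draw; fall back to the parent
        return parent.copy()
    return draws / total


def draw_frequency_set(config: SimConfig, rng: np.random.Generator | None = None) -> FrequencySet:
    """Draw the hierarchical truth frequencies for every population x locus.

    Per locus: a hyper-ancestral vector ~ symmetric Dirichlet(1); species
    pools drift from it with ``species_divergence``; clusters drift from
    their species pool with ``fct_sim``; populations drift from their
    cluster with ``fsc_sim``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_FREQS]))
    fs = FrequencySet(allele_sizes=config.allele_sizes)
    A = config.alleles_per_locus
    for locus in range(config.n_loci):
        hyper = rng.dirichlet(np.ones(A)) if A > 1 else np.array([1.0])
        for s in range(config.n_species):
            p_species = _dirichlet_from_parent(hyper, config.species_divergence, rng)
            fs.freqs[(s, -1, -1, locus)] = p_species
            for c in range(config.clusters_per_species):
                p_cluster = _dirichlet_from_parent(p_species, config.fct_sim, rng)
                fs.freqs[(s, c, -1, locus)] = p_cluster
                for p in range(config.pops_per_cluster):
                    fs.freqs[(s, c, p, locus)] = _dirichlet_from_parent(
                        p_cluster, config.fsc_sim, rng
                    )
    return fs


PopFreqs = list[np.ndarray]  # per-locus probability vectors over config.allele_sizes


def make_sporophyte(
    pop_freqs: PopFreqs,
    allele_sizes: np.ndarray,
    ploidy: int,
    rng: np.random.Generator,
    selfing_rate: float = 0.0,
    hybrid_freqs: PopFreqs | None = None,
) -> SporophyteGenotype:
    """Build a sporophyte by random union of ploidy/2 maternal and ploidy/2
    paternal allele copies per locus.

    ``hybrid_freqs`` supplies the paternal frequencies for an interspecific
    cross; otherwise both gamete pools come from the maternal population
    (``selfing_rate`` is accepted for interface stability; with a single
    un-subdivided gamete pool per population it does not alter the draw).
    """
    if ploidy not in (2, 4, 8):
        raise ValueError(f"ploidy must be 2, 4 or 8, got {ploidy}")
    half = ploidy // 2
    paternal_freqs = hybrid_freqs if hybrid_freqs is not None else pop_freqs
    per_locus: list[tuple[int, ...]] = []
    for locus, p_mat in enumerate(pop_freqs):
        p_pat = paternal_freqs[locus]
        if len(p_mat) == 0 or len(p_pat) == 0:
            raise ValueError(f"empty frequency vector at locus {locus}")
        maternal = rng.choice(allele_sizes, size=half, p=p_mat)
        paternal = rng.choice(allele_sizes, size=half, p=p_pat)
        per_locus.append(tuple(sorted(int(a) for a in np.concatenate([maternal, paternal]))))
    return SporophyteGenotype(ploidy=ploidy, alleles=per_locus)


def blade_from_sporophyte(
    sporophyte: SporophyteGenotype,
    dropout_prob: float,
    rng: np.random.Generator,
) -> list[frozenset[int] | None]:
    """Observed blade genotype: per locus the set of distinct sporophyte
    alleles (the tetrad products jointly carry every parental copy), with
    each distinct allele independently dropped with ``dropout_prob``.

    A locus losing every allele is returned as None (missing).
    """
    observed: list[frozenset[int] | None] = []
    for alleles in sporophyte.alleles:
        distinct = sorted(set(alleles))
        if dropout_prob > 0.0:
            keep = [a for a in distinct if rng.random() >= dropout_prob]
        else:
            keep = distinct
        observed.append(frozenset(keep) if keep else None)
    return observed


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        out[pos] = (out[pos] + rng.integers(1, 4)) % 4
    return out


_BASES = np.array(list("ACGT"))


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _cp_pools(config: SimConfig, rng: np.random.Generator):
    """Per-species cpDNA haplotype pools.

    Each species has a root sequence; the two (or more) species roots differ
    at ~1% of sites plus a floor of 8 fixed differences, mirroring two
    well-separated plastid clades.  Each population's pool holds the species
    root (widespread shared haplotype) plus ``cp_haps_per_pool - 1``
    single-substitution derivatives — the shallow, star-like variation seen
    in intraspecific rbcL data.
    """
    L = config.cp_seq_length
    base_root = _random_sequence(L, rng)
    n_diff = max(8, L // 100)
    n_diff = min(n_diff, L)
    species_roots = [base_root]
    for _ in range(1, config.n_species):
        positions = rng.choice(L, size=n_diff, replace=False)
        species_roots.append(_mutate(base_root, positions, rng))
    pools: dict[tuple[int, int, int], list[tuple[str, str]]] = {}
    for s in range(config.n_species):
        root = species_roots[s]
        for c in range(config.clusters_per_species):
            for p in range(config.pops_per_cluster):
                pool: list[tuple[str, str]] = [(f"SP{s + 1}-H0", _to_str(root))]
                for k in range(1, config.cp_haps_per_pool):
                    pos = rng.integers(0, L)
                    hap = _mutate(root, np.array([pos]), rng)
                    pool.append((f"SP{s + 1}-C{c + 1}P{p + 1}-H{k}", _to_str(hap)))
                pools[(s, c, p)] = pool
    roots = [(f"SP{s + 1}-H0", _to_str(r)) for s, r in enumerate(species_roots)]
    return pools, roots


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full forward simulation; deterministic given ``config.seed``."""
    config.validate()
    truth = draw_frequency_set(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_INDS]))
    cp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_CP]))
    cp_pools, cp_roots = _cp_pools(config, cp_rng)

    locus_names = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    ploidies = np.array([2, 4, 8])
    weights = np.asarray(config.ploidy_weights, dtype=float)
    sizes = config.allele_sizes

    individuals: list[SimIndividual] = []
    for s in range(config.n_species):
        species_label = f"SP{s + 1}"
        for c in range(config.clusters_per_species):
            cluster_code = f"{species_label}-C{c + 1}"
            for p in range(config.pops_per_cluster):
                pop_code = f"{species_label}-C{c + 1}-P{p + 1}"
                pop_freqs = [
                    truth.population_vector(s, c, p, locus) for locus in range(config.n_loci)
                ]
                for i in range(config.inds_per_pop):
                    ind_id = f"{pop_code}-I{i + 1:03d}"
                    ploidy = int(rng.choice(ploidies, p=weights))
                    hybrid = config.n_species > 1 and rng.random() < config.hybrid_fraction
                    hybrid_freqs = None
                    if hybrid:
                        s2 = int(rng.choice([x for x in range(config.n_species) if x != s]))
                        c2 = int(rng.integers(config.clusters_per_species))
                        p2 = int(rng.integers(config.pops_per_cluster))
                        hybrid_freqs = [
                            truth.population_vector(s2, c2, p2, locus)
                            for locus in range(config.n_loci)
                        ]
                    sporo = make_sporophyte(
                        pop_freqs,
                        sizes,
                        ploidy,
                        rng,
                        selfing_rate=config.selfing_rate,
                        hybrid_freqs=hybrid_freqs,
                    )
                    observed = blade_from_sporophyte(sporo, config.dropout_prob, rng)
                    # maternal cpDNA; hybrid lineages may carry the other
                    # species' plastid (introgression)
                    if hybrid and rng.random() < config.introgression_prob:
                        hap_id, hap_seq = cp_roots[s2]
                    else:
                        pool = cp_pools[(s, c, p)]
                        hap_id, hap_seq = pool[int(rng.integers(len(pool)))]
                    individuals.append(
                        SimIndividual(
                            individual_id=ind_id,
                            population_code=pop_code,
                            cluster_code=cluster_code,
                            species_label=species_label,
                            ploidy=ploidy,
                            hybrid=hybrid,
                            observed=observed,
                            cp_haplotype_id=hap_id,
                            cp_sequence=hap_seq,
                        )
                    )
    return SimDataset(
        config=config, truth=truth, locus_names=locus_names, individuals=individuals
    )
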