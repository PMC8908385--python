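"""Assumed-ploidy recoding and maximum-likelihood allele-dosage correction.

Fragment analysis of a chimeric blade reports which allele sizes are
present at a locus, but not how many copies of each the underlying
sporophyte carried, nor the sporophyte's ploidy.  The strategy implemented
here analyses the same data under several *assumed* ploidies m in
{2, 4, 8}:

* ``recode_dataset`` retains at most m distinct alleles per individual x
  locus, subsampling uniformly (and reproducibly) when more were observed;
* ``em_allele_frequencies`` estimates population allele frequencies by an
  EM algorithm that sums over every dosage assignment compatible with the
  observed allele set, weighting by the random-union-of-gametes genotype
  prior at ploidy m (the Hardy-Weinberg analogue for polyploids).

At m = 2 dosage is never ambiguous and the EM reduces exactly to allele
counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from zlib import crc32

import numpy as np

__all__ = [
    "PloidyCoding",
    "RecodedCall",
    "AlleleFrequencyEstimate",
    "recode_dataset",
    "enumerate_compatible_genotypes",
    "em_allele_frequencies",
]


@dataclass(frozen=True)
class RecodedCall:
    alleles: tuple[int, ...]  # sorted, 1..m distinct sizes
    ambiguous_dosage: bool


@dataclass
class PloidyCoding:
    """A dataset recoded under assumed ploidy m.

    ``calls[individual_id][locus]`` is a RecodedCall, or None for missing.
    The subsample drawn for a cell depends only on (seed, individual_id,
    locus), never on processing order.
    """

    assumed_ploidy: int
    subsample_seed: int
    calls: dict[str, dict[str, RecodedCall | None]] = field(default_factory=dict)

    def retained(self, individual_id: str, locus: str) -> tuple[int, ...] | None:
        call = self.calls[individual_id].get(locus)
        return None if call is None else call.alleles

    def is_ambiguous(self, individual_id: str, locus: str) -> bool:
        call = self.calls[individual_id].get(locus)
        return bool(call is not None and call.ambiguous_dosage)


def _cell_rng(seed: int, individual_id: str, locus: str) -> np.random.Generator:
    """Stable per-cell RNG keyed by (seed, individual, locus)."""
    key = np.random.SeedSequence(
        [seed & 0x7FFFFFFF, crc32(individual_id.encode()), crc32(locus.encode())]
    )
    return np.random.default_rng(key)


def _recode_cell(
    observed: frozenset[int] | None, m: int, seed: int, individual_id: str, locus: str
) -> RecodedCall | None:
    if observed is None:
        return None
    ordered = tuple(sorted(observed))
    if len(ordered) > m:
        # uniform m-subset; subsets enumerated in lexicographic allele order
        # so the draw is reproducible and order-independent
        subsets = list(combinations(ordered, m))
        rng = _cell_rng(seed, individual_id, locus)
        ordered = subsets[int(rng.integers(len(subsets)))]
    ambiguous = 1 < len(ordered) < m
    return RecodedCall(alleles=ordered, ambiguous_dosage=ambiguous)


def recode_dataset(ds, m: int, seed: int = 0) -> PloidyCoding:
    """Recode every individual x locus under assumed ploidy m in {2, 4, 8}.

    Cells with more than m distinct observed alleles are subsampled to a
    uniform random m-subset, seeded per cell; all other cells are retained
    verbatim.  Missing stays missing; no allele is ever invented.
    """
    if m not in (2, 4, 8):
        raise ValueError(f"assumed ploidy must be 2, 4 or 8, got {m}")
    coding = PloidyCoding(assumed_ploidy=m, subsample_seed=seed)
    for ind in ds.individuals:
        coding.calls[ind.individual_id] = {
            locus: _recode_cell(ind.loci.get(locus), m, seed, ind.individual_id, locus)
            for locus in ds.locus_names
        }
    return coding


def _compositions(total: int, parts: int):
    """All orderings of ``parts`` positive integers summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_compatible_genotypes(allele_set, m: int) -> list[tuple[int, ...]]:
    """All dosage multisets of size m whose support is exactly the observed
    allele set: every observed allele gets >= 1 copy, nothing else appears.

    Returned as sorted tuples of allele sizes with repetition; there are
    C(m-1, k-1) of them for k observed alleles.
    """
    ordered = sorted(allele_set)
    k = len(ordered)
    if k == 0:
        raise ValueError("empty allele set")
    if k > m:
        raise ValueError(f"{k} observed alleles cannot fit in ploidy {m}")
    out = []
    for comp in _compositions(m, k):
        geno: list[int] = []
        for allele, count in zip(ordered, comp):
            geno.extend([allele] * count)
        out.append(tuple(geno))
    return out


@dataclass
class AlleleFrequencyEstimate:
    """EM estimate for one population x locus."""

    alleles: tuple[int, ...]
    probs: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_phenotypes: int
    log_likelihood_trace: tuple[float, ...] = ()

    def as_dict(self) -> dict[int, float]:
        return {a: float(p) for a, p in zip(self.alleles, self.probs)}


def _log_multinomial(counts: np.ndarray) -> float:
    m = counts.sum()
    return math.lgamma(m + 1) - sum(math.lgamma(c + 1) for c in counts)


def em_allele_frequencies(
    phenotypes,
    m: int,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> AlleleFrequencyEstimate:
    """ML allele frequencies under unknown dosage at assumed ploidy m.

    ``phenotypes`` is an iterable of allele sets (one per non-missing
    individual at one population x locus).  The genotype prior is the
    random union of m gametes at the current frequencies, restricted to
    multisets whose support matches the observed set; the E-step assigns
    each phenotype posterior weights over those multisets and the M-step
    re-estimates frequencies from the expected allele counts.  The
    log-likelihood is non-decreasing every iteration.
    """
    sets = [frozenset(p) for p in phenotypes if p]
    if not sets:
        raise ValueError("need at least one non-missing phenotype")
    if any(len(s) > m for s in sets):
        raise ValueError(f"phenotype with more than {m} alleles; recode first")

    alleles = tuple(sorted(set().union(*sets)))
    index = {a: i for i, a in enumerate(alleles)}
    A = len(alleles)
    n = len(sets)

    # group identical phenotypes; precompute compatible dosage count-vectors
    # and their multinomial coefficients
    groups: dict[frozenset[int], int] = {}
    for s in sets:
        groups[s] = groups.get(s, 0) + 1
    blocks = []
    for s, mult in sorted(groups.items(), key=lambda kv: sorted(kv[0])):
        genos = enumerate_compatible_genotypes(s, m)
        counts = np.zeros((len(genos), A))
        log_coef = np.zeros(len(genos))
        for g, geno in enumerate(genos):
            for a in geno:
                counts[g, index[a]] += 1
            log_coef[g] = _log_multinomial(counts[g][counts[g] > 0])
        blocks.append((mult, counts, log_coef))

    p = np.full(A, 1.0 / A)  # uniform over the observed alleles

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_p = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
        expected = np.zeros(A)
        ll = 0.0
        for mult, counts, log_coef in blocks:
            log_w = log_coef + counts @ log_p
            top = log_w.max()
            if top == -np.inf:  # phenotype impossible under current p
                ll = -np.inf
                w = np.full(len(log_w), 1.0 / len(log_w))
            else:
                w = np.exp(log_w - top)
                tot = w.sum()
                ll += mult * (top + math.log(tot))
                w /= tot
            expected += mult * (w @ counts)
        new_p = expected / (m * n)
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        trace.append(ll)
        if delta < tol:
            converged = True
            break

    # final log-likelihood at the converged frequencies
    with np.errstate(divide="ignore"):
        log_p = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
    ll = 0.0
    for mult, counts, log_coef in blocks:
        log_w = log_coef + counts @ log_p
        top = log_w.max()
        ll += mult * (top + math.log(np.exp(log_w - top).sum())) if top > -np.inf else -np.inf
    return AlleleFrequencyEstimate(
        alleles=alleles,
        probs=p,
        log_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
        n_phenotypes=n,
        log_likelihood_trace=tuple(trace),
    )
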