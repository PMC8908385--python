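"""Maximum-likelihood allele frequencies under unknown dosage.

A tetraploid phenotype {A, B} could be AAAB, AABB or ABBB; the EM weights
these by the random-union-of-gametes prior and re-estimates frequencies
from expected counts.
"""

from mixopop import em_allele_frequencies

# nine tetraploid-coded phenotypes at one locus of one population
phenotypes = [{120}, {120}, {120, 124}, {120, 124}, {120, 124},
              {124}, {120, 124, 128}, {120, 128}, {120}]
est = em_allele_frequencies(phenotypes, m=4)

print(f"converged in {est.n_iterations} iterations (LL = {est.log_likelihood:.3f})")
for allele, p in est.as_dict().items():
    print(f"  allele {allele}: {p:.4f}")

# Frequencies sum to 1 over the observed alleles; the log-likelihood is
# non-decreasing every iteration.  At assumed ploidy 2 the same routine
# reduces exactly to allele counting.
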