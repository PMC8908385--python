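"""Simulate a two-species chimeric, mixoploid microsatellite dataset.

Each simulated blade is the union of the four meiotic products of one
sporophyte, so at a locus it shows every distinct parental allele: up to 2
for a diploid sporophyte, 4 for a tetraploid, 8 for an octoploid.
"""

from collections import Counter

from mixopop import SimConfig, simulate_dataset

cfg = SimConfig(seed=42)
sim = simulate_dataset(cfg)

ploidies = Counter(ind.ploidy for ind in sim.individuals)
max_alleles = Counter(
    max((len(obs) for obs in ind.observed if obs is not None), default=0)
    for ind in sim.individuals
)
print(f"simulated {len(sim.individuals)} blades in {len(sim.population_codes)} populations")
print(f"sporophyte ploidies (2x/4x/8x): {ploidies[2]}/{ploidies[4]}/{ploidies[8]}")
print("max distinct alleles per blade:", dict(sorted(max_alleles.items())))
print(f"hybrids: {sum(ind.hybrid for ind in sim.individuals)}")

# The ploidy histogram shows the mixoploid composition; the allele-count
# histogram is the observable signature: blades from higher-ploidy
# sporophytes can show more distinct alleles per locus (capped by dropout
# and shared ancestry), which is exactly why dosage is unknowable from
# fragment presence alone.
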