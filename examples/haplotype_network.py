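"""Collapse cpDNA sequences into haplotypes and draw their mutation-step
network, with a step cap that leaves divergent haplotypes unconnected.
"""

import networkx as nx

from mixopop import collapse_haplotypes, minimum_spanning_network, pairwise_steps
from mixopop.dataio import SequenceAlignment, SequenceRecord

# a toy alignment: a common haplotype, two one-step derivatives, and one
# divergent sequence (e.g. a cryptic lineage)
seqs = {
    "ind1": ("NORTH", "ACGTACGTACGTACGT"),
    "ind2": ("NORTH", "ACGTACGTACGTACGT"),
    "ind3": ("SOUTH", "ACGTACGTACGTACGA"),
    "ind4": ("SOUTH", "ACGTACGAACGTACGT"),
    "ind5": ("SOUTH", "TTTTACCTAGGTACCT"),
}
aln = SequenceAlignment(
    [SequenceRecord(i, loc, s) for i, (loc, s) in seqs.items()]
)

table = collapse_haplotypes(aln)
print(f"{table.n_haplotypes} haplotypes from {table.total_records} sequences")
print(table.counts_by_location.to_string())
print("mutation steps:")
print(pairwise_steps(table).to_string())

net = minimum_spanning_network(table, max_steps=5)
print("edges:", [(a, b, d["steps"]) for a, b, d in net.edges(data=True)])
print("components:", nx.number_connected_components(net))
# Haplotype D sits more than 5 steps from everything else, so the capped
# network leaves it isolated instead of forcing a long connection.
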