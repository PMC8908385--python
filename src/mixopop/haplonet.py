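"""cpDNA haplotype analysis: collapse aligned sequences into haplotypes,
tabulate their frequencies by sampling location and species, and build a
mutation-step minimum-spanning network.

The network keeps every edge tying the minimal inter-component distance at
each growth step (a network, not a tree) and supports an optional step cap
standing in for a statistical-parsimony connection limit: haplotypes more
than ``max_steps`` mutations from everything else stay disconnected.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import SequenceAlignment

__all__ = [
    "HaplotypeTable",
    "collapse_haplotypes",
    "pairwise_steps",
    "minimum_spanning_network",
    "write_edge_list",
]

_UNAMBIGUOUS = set("ACGT-")


def _haplotype_label(index: int) -> str:
    """A, B, ..., Z, AA, AB, ... in order of first appearance."""
    letters = string.ascii_uppercase
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = letters[rem] + label
    return label


@dataclass
class HaplotypeTable:
    labels: list[str]
    representatives: dict[str, str]  # label -> full-length representative sequence
    members: dict[str, list[str]]  # label -> record ids
    counts_by_location: pd.DataFrame  # locations x haplotypes
    counts_by_species: pd.DataFrame | None
    compared_sites: np.ndarray  # boolean mask over alignment columns
    record_haplotype: dict[str, str] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def total_records(self) -> int:
        return int(self.counts_by_location.to_numpy().sum())


def collapse_haplotypes(
    aln: SequenceAlignment,
    ambiguous_policy: str = "exclude-site",
    species_of_location: dict[str, str] | None = None,
    treat_gaps_as_state: bool = True,
) -> HaplotypeTable:
    """Merge identical sequences into haplotypes labelled A, B, ... in order
    of first appearance.

    ``ambiguous_policy``:
      * ``"exclude-site"`` (default): alignment columns where any record
        carries an N/IUPAC-ambiguous base are excluded from comparison;
      * ``"strict"``: sequences compared verbatim.

    Gaps are a fifth character state by default; with
    ``treat_gaps_as_state=False`` gapped columns are excluded like
    ambiguous ones.
    """
    if not aln.records:
        raise ValueError("empty alignment")
    if ambiguous_policy not in ("exclude-site", "strict"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    L = aln.length
    mask = np.ones(L, dtype=bool)
    if ambiguous_policy == "exclude-site":
        allowed = _UNAMBIGUOUS if treat_gaps_as_state else set("ACGT")
        for rec in aln.records:
            for j, ch in enumerate(rec.sequence):
                if ch not in allowed:
                    mask[j] = False

    keys: dict[str, str] = {}  # comparison key -> label
    labels: list[str] = []
    representatives: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    record_haplotype: dict[str, str] = {}
    loc_counts: dict[tuple[str, str], int] = {}
    sp_counts: dict[tuple[str, str], int] = {}
    for rec in aln.records:
        key = "".join(ch for ch, keep in zip(rec.sequence, mask) if keep)
        if key not in keys:
            label = _haplotype_label(len(labels))
            keys[key] = label
            labels.append(label)
            representatives[label] = rec.sequence
            members[label] = []
        label = keys[key]
        members[label].append(rec.id)
        record_haplotype[rec.id] = label
        loc_counts[(rec.location_code, label)] = loc_counts.get((rec.location_code, label), 0) + 1
        if species_of_location is not None:
            sp = species_of_location.get(rec.location_code, "unknown")
            sp_counts[(sp, label)] = sp_counts.get((sp, label), 0) + 1

    locations = sorted({loc for loc, _ in loc_counts})
    loc_frame = pd.DataFrame(0, index=locations, columns=labels)
    for (loc, label), n in loc_counts.items():
        loc_frame.loc[loc, label] = n
    sp_frame = None
    if species_of_location is not None:
        species = sorted({sp for sp, _ in sp_counts})
        sp_frame = pd.DataFrame(0, index=species, columns=labels)
        for (sp, label), n in sp_counts.items():
            sp_frame.loc[sp, label] = n
    return HaplotypeTable(
        labels=labels,
        representatives=representatives,
        members=members,
        counts_by_location=loc_frame,
        counts_by_species=sp_frame,
        compared_sites=mask,
        record_haplotype=record_haplotype,
    )


def pairwise_steps(table: HaplotypeTable) -> pd.DataFrame:
    """Hamming distances (mutation steps) between haplotype representatives
    over the compared sites."""
    labels = table.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 haplotypes")
    seqs = {
        lab: np.frombuffer(
            "".join(
                ch for ch, keep in zip(table.representatives[lab], table.compared_sites) if keep
            ).encode(),
            dtype="S1",
        )
        for lab in labels
    }
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = int(np.sum(seqs[a] != seqs[b]))
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def minimum_spanning_network(
    table: HaplotypeTable, max_steps: int | None = None
) -> nx.Graph:
    """Minimum-spanning network over haplotypes.

    Kruskal-style growth over edges in increasing mutation-step order: at
    each distance class, *all* edges joining components that were distinct
    before the class is processed are added (ties kept), then components
    merge.  Edges longer than ``max_steps`` are excluded, so divergent
    haplotypes can remain isolated.
    """
    if max_steps is not None and max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    dist = pairwise_steps(table) if len(table.labels) > 1 else None
    g = nx.Graph()
    counts = table.counts_by_location.sum(axis=0)
    for lab in table.labels:
        g.add_node(lab, count=int(counts.get(lab, 0)))
    if dist is None:
        return g
    labels = table.labels
    edges = [
        (int(dist.loc[a, b]), a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    ]
    if max_steps is not None:
        edges = [e for e in edges if e[0] <= max_steps]
    edges.sort(key=lambda e: e[0])

    comp = {lab: lab for lab in labels}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    i = 0
    while i < len(edges):
        d = edges[i][0]
        batch = []
        while i < len(edges) and edges[i][0] == d:
            batch.append(edges[i])
            i += 1
        # membership is frozen before the class is processed: every edge
        # between then-distinct components at this distance is kept
        frozen = {lab: find(lab) for lab in labels}
        added = []
        for steps, a, b in batch:
            if frozen[a] != frozen[b]:
                g.add_edge(a, b, steps=steps)
                added.append((a, b))
        for a, b in added:
            ra, rb = find(a), find(b)
            if ra != rb:
                comp[ra] = rb
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["haplotype_a", "haplotype_b", "steps"])
        for a, b, data in sorted(graph.edges(data=True)):
            writer.writerow([a, b, data["steps"]])
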