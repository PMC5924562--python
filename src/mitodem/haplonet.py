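"""Haplotype collapsing and temporal / minimum-spanning networks.

Sequences are collapsed to haplotypes over the effective (complete-deletion)
columns shared with the summary-statistics module.  The network built here
is a minimum-spanning network: the union of every minimum spanning tree of
the complete Hamming-distance graph, computed by admitting, at each Kruskal
distance tier, every tie edge that joins two distinct components before
merging.  (A median-joining network additionally infers unsampled median
haplotypes; those inferred nodes are deliberately not added here.)
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .sumstats import TemporalAlignment, effective_columns

__all__ = [
    "HaplotypeTable",
    "collapse",
    "temporal_shared",
    "pairwise_steps",
    "min_spanning_network",
]


@dataclass
class HaplotypeTable:
    """Haplotypes with per-layer counts.

    ``representatives`` is an (h, L_eff) byte matrix of distinct haplotype
    sequences over effective columns; ``counts`` a (h x layers) DataFrame,
    indexed by haplotype id ``H1..Hh`` in order of first appearance.
    """

    representatives: np.ndarray
    counts: pd.DataFrame
    ages: dict[str, float]

    @property
    def h(self) -> int:
        return self.representatives.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def layers(self) -> list[str]:
        return list(self.counts.columns)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sequences(self) -> list[str]:
        return [bytes(row).decode() for row in self.representatives]


def collapse(alignment: TemporalAlignment, policy: str = "complete_deletion") -> HaplotypeTable:
    """Group identical sequences (over effective columns) into haplotypes."""
    if alignment.n < 1:
        raise ValueError("need at least one sequence")
    keep = effective_columns(alignment, policy)
    mat = alignment.matrix[:, keep]
    _, first_idx, inverse = np.unique(mat, axis=0, return_index=True, return_inverse=True)
    # re-order haplotypes by first appearance in the alignment
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    inverse = rank[inverse]
    reps = mat[np.sort(first_idx)]

    layers = list(dict.fromkeys(alignment.layers))
    h = reps.shape[0]
    counts = pd.DataFrame(
        0, index=[f"H{i + 1}" for i in range(h)], columns=layers, dtype=int
    )
    for hap_idx, layer in zip(inverse, alignment.layers):
        counts.iloc[int(hap_idx), counts.columns.get_loc(layer)] += 1
    return HaplotypeTable(representatives=reps, counts=counts, ages=dict(alignment.ages))


def temporal_shared(table: HaplotypeTable) -> tuple[int, pd.DataFrame]:
    """Haplotypes observed in more than one time layer.

    Returns the count and a boolean presence matrix (haplotype x layer).
    """
    if len(table.layers) < 2:
        raise ValueError("temporal sharing needs >= 2 layers")
    presence = table.counts > 0
    shared = int((presence.sum(axis=1) > 1).sum())
    return shared, presence


def pairwise_steps(table: HaplotypeTable) -> np.ndarray:
    """(h, h) matrix of Hamming distances (mutational steps) between
    haplotype representatives."""
    if table.h < 2:
        raise ValueError("need >= 2 haplotypes")
    reps = table.representatives
    h = table.h
    d = np.zeros((h, h), dtype=int)
    for i in range(h):
        diff = (reps[i + 1 :] != reps[i]).sum(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def min_spanning_network(table: HaplotypeTable) -> nx.Graph:
    """Union of all minimum spanning trees of the haplotype distance graph.

    Kruskal with tie tiers: at each distinct distance value, every edge
    joining two currently distinct components is admitted, and only then are
    the components merged.  Every edge of every MST appears in the result.
    """
    d = pairwise_steps(table)
    ids = list(table.counts.index)
    h = table.h
    g = nx.Graph()
    totals = table.total_counts()
    for i, hid in enumerate(ids):
        g.add_node(
            hid,
            size=int(totals.iloc[i]),
            **{f"n_{layer}": int(table.counts.iloc[i][layer]) for layer in table.layers},
        )

    edges = [(int(d[i, j]), i, j) for i in range(h) for j in range(i + 1, h)]
    edges.sort(key=lambda e: e[0])
    uf = list(range(h))

    def find(x: int) -> int:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        tier = []
        while pos < len(edges) and edges[pos][0] == w:
            tier.append(edges[pos])
            pos += 1
        admitted = [(i, j) for _, i, j in tier if find(i) != find(j)]
        for i, j in admitted:
            g.add_edge(ids[i], ids[j], weight=w, in_msn=True)
        for i, j in admitted:
            ri, rj = find(i), find(j)
            if ri != rj:
                uf[ri] = rj
    return g
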