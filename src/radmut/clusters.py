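"""Clustered point-mutation detection via the 1 kb pairwise graph.

Mutations of one clone are nodes; an edge joins two mutations on the same
chromosome at a genomic distance strictly below the threshold. Connected
components of size >= 2 are the clusters; components larger than 5 members
are kataegis-like showers, the rest omikli-like fog. Because edges chain,
a component can span more than the threshold end to end.

The implementation is a linear sweep over sorted positions: on a sorted
array, any pair bridging a gap >= threshold between consecutive positions
is itself >= threshold apart, so components are maximal runs split at such
gaps, and edges are enumerated with a two-pointer window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogs import SBS6_CATEGORIES
from .classify import classify_snv_6


@dataclass
class ClusterComponent:
    clone_id: str
    chrom: str
    positions: list[int]          # sorted, 1-based
    edges: list[tuple[int, int]]  # unordered member pairs at distance < threshold
    large_threshold: int = 5

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def cluster_class(self) -> str:
        return "kataegis_like" if self.size > self.large_threshold else "omikli_like"


@dataclass
class CloneClusters:
    clone_id: str
    threshold: int
    components: list[ClusterComponent] = field(default_factory=list)

    @property
    def clustered_mutation_count(self) -> int:
        return sum(c.size for c in self.components)


def find_clusters(
    positions_by_chrom: dict[str, list[int]],
    clone_id: str,
    threshold: int = 1000,
    large_threshold: int = 5,
) -> CloneClusters:
    """Cluster one clone's point mutations; singletons are discarded."""
    result = CloneClusters(clone_id=clone_id, threshold=threshold)
    for chrom, raw in positions_by_chrom.items():
        pos = np.sort(np.asarray(raw, dtype=np.int64))
        if pos.size == 0:
            continue
        gaps = np.diff(pos)
        breaks = np.nonzero(gaps >= threshold)[0]
        start = 0
        for b in list(breaks) + [pos.size - 1]:
            run = pos[start : b + 1]
            start = b + 1
            if run.size < 2:
                continue
            edges = []
            j = 0
            for i in range(run.size):
                if j <= i:
                    j = i + 1
                while j < run.size and run[j] - run[i] < threshold:
                    j += 1
                for k in range(i + 1, j):
                    edges.append((int(run[i]), int(run[k])))
            result.components.append(
                ClusterComponent(
                    clone_id=clone_id,
                    chrom=chrom,
                    positions=[int(p) for p in run],
                    edges=edges,
                    large_threshold=large_threshold,
                )
            )
    return result


def classify_components(components: list[ClusterComponent],
                        large_threshold: int = 5) -> dict[str, int]:
    counts = {"omikli_like": 0, "kataegis_like": 0}
    for c in components:
        if c.size > large_threshold:
            counts["kataegis_like"] += 1
        else:
            counts["omikli_like"] += 1
    return counts


def intermutation_distances(
    components: list[ClusterComponent], mode: str = "edges"
) -> list[int]:
    """Distances between clustered mutations, each unordered pair counted once.

    ``edges``: one distance per graph edge (pairs < threshold).
    ``consecutive``: distances between consecutive members of a component.
    """
    out: list[int] = []
    for c in components:
        if mode == "edges":
            out.extend(b - a for a, b in c.edges)
        elif mode == "consecutive":
            out.extend(
                int(b - a) for a, b in zip(c.positions, c.positions[1:])
            )
        else:
            raise ValueError(f"unknown distance mode {mode!r}")
    return out


def clustered_spectrum(
    components: list[ClusterComponent],
    snv_alleles: dict[tuple[str, int], tuple[str, str]],
) -> dict[str, int]:
    """6-class spectrum restricted to clustered SNVs.

    ``snv_alleles`` maps (chrom, pos) -> (ref, alt); clustered members
    missing from it (e.g. indels clustered by flag) are skipped.
    """
    spec = {c: 0 for c in SBS6_CATEGORIES}
    for comp in components:
        for p in comp.positions:
            alleles = snv_alleles.get((comp.chrom, p))
            if alleles is None:
                continue
            spec[classify_snv_6(*alleles)] += 1
    return spec


def brute_force_clusters(
    positions_by_chrom: dict[str, list[int]],
    clone_id: str,
    threshold: int = 1000,
    large_threshold: int = 5,
) -> CloneClusters:
    """O(n^2) all-pairs + graph-components reference implementation.

    Independent of the sweep: builds the full adjacency with networkx and
    reads off connected components. Used as the equivalence oracle.
    """
    import networkx as nx

    result = CloneClusters(clone_id=clone_id, threshold=threshold)
    for chrom, raw in positions_by_chrom.items():
        pos = sorted(int(p) for p in raw)
        g = nx.Graph()
        g.add_nodes_from(pos)
        arr = np.asarray(pos, dtype=np.int64)
        if arr.size >= 2:
            d = np.abs(arr[:, None] - arr[None, :])
            ii, jj = np.nonzero((d < threshold) & np.triu(np.ones_like(d, dtype=bool), 1))
            g.add_edges_from((int(arr[i]), int(arr[j])) for i, j in zip(ii, jj))
        for comp in nx.connected_components(g):
            members = sorted(comp)
            if len(members) < 2:
                continue
            edges = sorted(
                (min(a, b), max(a, b)) for a, b in g.edges(members) if a in comp and b in comp
            )
            result.components.append(
                ClusterComponent(
                    clone_id=clone_id,
                    chrom=chrom,
                    positions=members,
                    edges=edges,
                    large_threshold=large_threshold,
                )
            )
    result.components.sort(key=lambda c: (c.chrom, c.positions[0]))
    return result
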