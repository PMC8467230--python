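"""Haplotype collapsing and minimum spanning networks.

Jointly aligned sequences (consensuses plus references of one species)
collapse into haplotypes by exact row identity; haplotypes are named
"Hap 1", "Hap 2", ... by decreasing frequency (ties by first appearance).
The network over haplotypes uses the integer mutational distance (count of
differing gap-free columns) and, at epsilon = 0, equals the union of all
minimum spanning trees of the complete distance graph, built by Kruskal
with distance classes processed against components frozen at the start of
each class.  For epsilon > 0 each pair's admission threshold is relaxed by
epsilon distance units beyond the class at which its endpoints first
connect, so the network grows monotonically with epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import align


@dataclass
class HaplotypeMember:
    seq_id: str
    source: str                   # "SAN" or "PacBio"
    n_reads: Optional[int] = None  # read count for PacBio consensuses

    def label(self) -> str:
        if self.source == "SAN":
            return f"{self.seq_id} (SAN)"
        return f"{self.seq_id} ({self.n_reads})"


@dataclass
class Haplotype:
    name: str                      # "Hap 1", ...
    row: str                       # aligned (gapped) sequence
    members: List[HaplotypeMember]

    @property
    def frequency(self) -> int:
        return len(self.members)

    @property
    def source_class(self) -> str:
        sources = {m.source for m in self.members}
        if sources == {"SAN"}:
            return "sanger_only"
        if sources == {"PacBio"}:
            return "pacbio_only"
        return "both"


@dataclass
class HaplotypeNetwork:
    haplotypes: List[Haplotype]
    edges: List[Tuple[str, str, int]]  # (hap name, hap name, steps)


def collapse_haplotypes(rows: Sequence[str],
                        members: Sequence[HaplotypeMember]
                        ) -> List[Haplotype]:
    """Merge identical aligned rows into frequency-ranked haplotypes."""
    if not rows:
        raise ValueError("no sequences to collapse")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be jointly aligned (equal length)")
    groups: Dict[str, List[HaplotypeMember]] = {}
    first_seen: Dict[str, int] = {}
    for i, (row, mem) in enumerate(zip(rows, members)):
        groups.setdefault(row, []).append(mem)
        first_seen.setdefault(row, i)
    ordered = sorted(groups, key=lambda r: (-len(groups[r]), first_seen[r]))
    return [Haplotype(name=f"Hap {k}", row=row, members=groups[row])
            for k, row in enumerate(ordered, start=1)]


def mutational_distance(row_a: str, row_b: str) -> int:
    """Differing columns among columns where neither row has a gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)
    gap = b"-"[0]
    scored = (a != gap) & (b != gap)
    return int(((a != b) & scored).sum())


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _first_connection_classes(n: int,
                              dist: Dict[Tuple[int, int], int]
                              ) -> np.ndarray:
    """T[i, j] = distance class at which i and j first share a component
    under the frozen-component Kruskal process."""
    T = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(T, 0)
    dsu = _DSU(n)
    for d in sorted(set(dist.values())):
        # admit within the class against components frozen at class start
        frozen = [dsu.find(i) for i in range(n)]
        for (i, j), dij in dist.items():
            if dij == d and frozen[i] != frozen[j]:
                dsu.union(i, j)
        for i, j in combinations(range(n), 2):
            if T[i, j] < 0 and dsu.find(i) == dsu.find(j):
                T[i, j] = T[j, i] = d
    return T


def msn_edge_indices(n: int, dist: Dict[Tuple[int, int], int],
                     epsilon: int = 0) -> List[Tuple[int, int, int]]:
    """MSN edge set over ``n`` nodes with pairwise distances ``dist``
    (keys (i, j), i < j).  An edge is admitted iff its distance is within
    ``epsilon`` of the class at which its endpoints first connect under
    the frozen-component Kruskal process; epsilon = 0 is exactly the
    union of all minimum spanning trees."""
    if n < 1:
        raise ValueError("need at least one node")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if n == 1:
        return []
    T = _first_connection_classes(n, dist)
    return [(i, j, d) for (i, j), d in sorted(dist.items())
            if d <= T[i, j] + epsilon]


def build_msn(haplotypes: Sequence[Haplotype], epsilon: int = 0
              ) -> HaplotypeNetwork:
    """Minimum spanning network over the haplotypes' mutational distances.

    epsilon = 0 yields exactly the union of all minimum spanning trees;
    larger epsilon admits every pair within epsilon distance units of the
    class at which its endpoints first connect.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    n = len(haplotypes)
    dist = {(i, j): mutational_distance(haplotypes[i].row, haplotypes[j].row)
            for i, j in combinations(range(n), 2)}
    edges = [(haplotypes[i].name, haplotypes[j].name, d)
             for i, j, d in msn_edge_indices(n, dist, epsilon)]
    return HaplotypeNetwork(list(haplotypes), edges)


def network_report(network: HaplotypeNetwork
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype table (name, frequency, member list, source class) and
    edge list (endpoints, mutational steps)."""
    hap_df = pd.DataFrame([{
        "haplotype": h.name,
        "frequency": h.frequency,
        "sequences": "; ".join(m.label() for m in h.members),
        "source_class": h.source_class,
    } for h in network.haplotypes])
    edge_df = pd.DataFrame(network.edges,
                           columns=["hap_a", "hap_b", "steps"])
    return hap_df, edge_df
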