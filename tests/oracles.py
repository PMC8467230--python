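"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the alignment
oracle is a plain tuple-valued dynamic programme, the network oracle
enumerates minimum spanning trees with networkx, and hamming/p-distance
helpers work directly on character lists.
"""

from itertools import combinations
from typing import Dict, FrozenSet, Set, Tuple

import networkx as nx


def nw_cost_gaps(a: str, b: str) -> Tuple[int, int]:
    """Global alignment with unit mismatch/gap costs; returns the minimum
    cost and, among minimum-cost alignments, the minimum number of gap
    columns (lexicographic tuple DP — substitutions preferred over
    indels at equal cost)."""
    prev = [(j, j) for j in range(len(b) + 1)]
    for i in range(1, len(a) + 1):
        cur = [(i, i)]
        for j in range(1, len(b) + 1):
            mism = int(a[i - 1] != b[j - 1])
            cur.append(min(
                (prev[j - 1][0] + mism, prev[j - 1][1]),
                (prev[j][0] + 1, prev[j][1] + 1),
                (cur[j - 1][0] + 1, cur[j - 1][1] + 1),
            ))
        prev = cur
    return prev[-1]


def nw_cost_mismatches(a: str, b: str) -> Tuple[int, int]:
    cost, gaps = nw_cost_gaps(a, b)
    return cost, cost - gaps


def nw_identity(a: str, b: str) -> float:
    cost, gaps = nw_cost_gaps(a, b)
    matches = (len(a) + len(b) + gaps) // 2 - cost
    return matches / min(len(a), len(b))


def nw_p_distance(a: str, b: str) -> float:
    cost, gaps = nw_cost_gaps(a, b)
    mism = cost - gaps
    matches = (len(a) + len(b) + gaps) // 2 - cost
    return mism / (matches + mism)


def mst_union(n: int, dist: Dict[Tuple[int, int], int]
              ) -> Set[FrozenSet[int]]:
    """Union of the edge sets of ALL minimum spanning trees, enumerated
    with networkx's spanning-tree iterator (ascending total weight)."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (i, j), d in dist.items():
        g.add_edge(i, j, weight=d)
    edges: Set[FrozenSet[int]] = set()
    best = None
    for tree in nx.SpanningTreeIterator(g, minimum=True):
        w = tree.size(weight="weight")
        if best is None:
            best = w
        if w > best + 1e-9:
            break
        edges |= {frozenset((u, v)) for u, v in tree.edges()}
    return edges


def scan_primer_site(seq: str, site: str) -> Tuple[int, int]:
    """Exhaustive scan: (leftmost argmin offset, min mismatches)."""
    best = (0, len(site) + 1)
    for off in range(len(seq) - len(site) + 1):
        mm = sum(x != y for x, y in zip(seq[off:off + len(site)], site))
        if mm < best[1]:
            best = (off, mm)
    return best
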