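"""Greedy identity clustering, per-cluster star alignment, majority-rule
consensus, and major-variant selection.

The clustering follows the greedy longest-first scheme of the standard
identity-clustering tools: sequences sorted by decreasing length (ties by
id) each join the first existing cluster whose *representative* they match
at or above the identity threshold, else found a new cluster.  Identity is
match columns of the canonical global alignment divided by the shorter
sequence's length (the clustering tools' documented convention; alignment-
length denominator available as a config switch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import align
from .records import SequenceRecord


def pairwise_identity(a: str, b: str, denominator: str = "shorter") -> float:
    """Fraction of matching columns of the canonical global alignment,
    over the shorter sequence's length (default) or the alignment length."""
    st = align.edit_stats(a, b)
    if denominator == "alignment":
        return st.identity_alignment_denominator
    return st.identity


def _identity_reaches(a: str, b: str, threshold: float,
                      denominator: str) -> bool:
    """Exact threshold decision, short-circuited by edit-distance bounds
    (sound: the exact DP only runs when the bounds straddle the cut)."""
    if denominator == "shorter":
        lo, hi = align.identity_bounds(a, b)
        if lo >= threshold:
            return True
        if hi < threshold:
            return False
    return pairwise_identity(a, b, denominator) >= threshold


@dataclass
class Cluster:
    representative: SequenceRecord
    members: List[SequenceRecord]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusRecord:
    """Per-cluster consensus; ids number clusters by decreasing size."""

    id: str          # "<sample>-C<k>", k from 1 by decreasing cluster size
    seq: str
    n_reads: int
    region: str      # "ITS" or "LSU"
    sample: str


def greedy_cluster(seqs: Sequence[SequenceRecord], threshold: float = 0.97,
                   denominator: str = "shorter") -> List[Cluster]:
    """Greedy longest-first clustering at the given identity threshold.

    Deterministic: input sorted by (length desc, id); a sequence joins the
    first (oldest) cluster whose representative it matches.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    clusters: List[Cluster] = []
    for rec in ordered:
        for cl in clusters:
            if _identity_reaches(rec.seq, cl.representative.seq, threshold,
                                 denominator):
                cl.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


def align_cluster(cluster: Cluster) -> List[str]:
    """Star alignment of the members against the representative.

    Returns gapped rows in member order; the representative's row is the
    one at the representative's index in ``cluster.members``.
    """
    seqs = [m.seq for m in cluster.members]
    rep_idx = next(i for i, m in enumerate(cluster.members)
                   if m.id == cluster.representative.id)
    return align.star_align(seqs, reference_index=rep_idx)


def consensus(aligned: Sequence[str], weights: Optional[Sequence[float]] = None,
              representative_row: int = 0) -> str:
    """Majority-rule consensus of equal-length gapped rows.

    Per column the (weighted) majority symbol over {A, C, G, T, N, -} wins;
    ties break toward the representative row's symbol (else the
    lexicographically smallest tied symbol); gap-majority columns are
    deleted and the result is ungapped.
    """
    if not aligned:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in aligned}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    mat = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8)
                    for r in aligned])
    w = np.ones(len(aligned)) if weights is None else np.asarray(
        weights, dtype=float)
    symbols = np.frombuffer(b"-ACGTN", dtype=np.uint8)
    scores = np.zeros((len(symbols), mat.shape[1]))
    for si, s in enumerate(symbols):
        scores[si] = ((mat == s) * w[:, None]).sum(axis=0)
    best = scores.max(axis=0)
    rep = mat[representative_row]
    out = []
    for j in range(mat.shape[1]):
        tied = symbols[scores[:, j] == best[j]]
        if rep[j] in tied:
            sym = rep[j]
        else:
            sym = np.sort(tied)[0] if b"-"[0] not in tied else b"-"[0]
        if sym != b"-"[0]:
            out.append(sym)
    return bytes(out).decode("ascii")


def consensus_records(clusters: Sequence[Cluster], sample: str, region: str
                      ) -> List[ConsensusRecord]:
    """Consensus per cluster, numbered C1, C2, ... by decreasing size
    (ties by founding order)."""
    order = sorted(range(len(clusters)),
                   key=lambda i: (-clusters[i].size, i))
    out = []
    for rank, i in enumerate(order, start=1):
        cl = clusters[i]
        rows = align_cluster(cl)
        rep_row = next(j for j, m in enumerate(cl.members)
                       if m.id == cl.representative.id)
        seq = consensus(rows, representative_row=rep_row)
        out.append(ConsensusRecord(id=f"{sample}-C{rank}", seq=seq,
                                   n_reads=cl.size, region=region,
                                   sample=sample))
    return out


def select_major(consensuses: Sequence[ConsensusRecord]) -> ConsensusRecord:
    """The consensus with the most reads (the major variant); ties break
    toward the lowest cluster index."""
    if not consensuses:
        raise ValueError("no consensus records")
    return max(consensuses,
               key=lambda c: (c.n_reads, -int(c.id.rsplit("-C", 1)[1])))
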