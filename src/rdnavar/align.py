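"""Pairwise global alignment statistics and star multiple alignment.

The clustering identity and the p-distance both reduce to two scalars of a
global alignment with unit mismatch/gap costs: the edit cost ``k`` and the
number of gap columns ``G``.  Optimal-cost alignments are not unique, so
the canonical alignment used throughout is the minimum-cost alignment with
the fewest gap columns — substitutions are preferred over indels at equal
cost, as an aligner with gap penalties would, which keeps the measures
faithful to substitution-generated divergence.  ``(k, G)`` is well defined
and symmetric, and every derived measure is deterministic:

* mismatches       ``X = k - G``
* matches          ``M = (len_a + len_b + G) / 2 - k``
* identity         ``M / min(len_a, len_b)``   (clustering-tool convention)
* p-distance       ``X / (M + X)``             (pairwise deletion: gap
  columns are excluded from the denominator)

``edit_stats`` computes ``(k, G)`` with a vectorised dynamic programme over
values packed as ``cost * BIG + gaps`` so a single lexicographic minimum
drives both objectives.  Alignment *paths* (needed only for star
alignment, where the exact gap placement matters but the column counts do
not) come from edlib's banded aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import edlib
import numpy as np

# Packs (cost, gap columns) into one int64; gaps < BIG for any sequence
# far shorter than a megabase.
_BIG = np.int64(1) << np.int64(20)


@dataclass(frozen=True)
class EditStats:
    """Canonical global-alignment column counts for a sequence pair."""

    cost: int        # minimum unit-cost edit distance
    mismatches: int  # mismatch columns of the canonical alignment
    matches: int     # match columns of the canonical alignment
    len_a: int
    len_b: int

    @property
    def scored_columns(self) -> int:
        """Columns where neither row has a gap."""
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        return self.matches / min(self.len_a, self.len_b)

    @property
    def identity_alignment_denominator(self) -> float:
        n_cols = self.scored_columns + (self.cost - self.mismatches)
        return self.matches / n_cols

    @property
    def p_distance(self) -> float:
        scored = self.scored_columns
        if scored == 0:
            raise ValueError("no gap-free columns: p-distance undefined")
        return self.mismatches / scored


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def edit_stats(a: str, b: str) -> EditStats:
    """Exact ``(cost, gap columns)`` of the canonical global alignment.

    Needleman-Wunsch with unit costs over the packed objective
    ``cost * BIG + gaps`` (mismatch adds BIG, a gap adds BIG + 1); the
    horizontal (gap) recurrence is resolved with a running minimum so each
    row is a handful of vector ops.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    av, bv = _encode(a), _encode(b)
    if len(av) > len(bv):  # fewer DP rows; measures are symmetric
        av, bv = bv, av
    m = len(bv)
    gap_pen = _BIG + np.int64(1)
    gap_ramp = np.arange(m + 1, dtype=np.int64) * gap_pen
    prev = gap_ramp.copy()
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, len(av) + 1):
        sub = np.where(bv == av[i - 1], np.int64(0), _BIG)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = prev[0] + gap_pen
        np.minimum(prev[:-1] + sub, prev[1:] + gap_pen, out=cand[1:])
        # cur[j] = min_{t<=j} cand[t] + (j-t)*gap_pen
        np.subtract(cand, gap_ramp, out=cur)
        np.minimum.accumulate(cur, out=cur)
        cur += gap_ramp
        prev, cur = cur, prev
    packed = int(prev[m])
    cost, gaps = divmod(packed, int(_BIG))
    mism = cost - gaps
    matches = (len(a) + len(b) + gaps) // 2 - cost
    return EditStats(cost, mism, matches, len(a), len(b))


def edit_distance(a: str, b: str) -> int:
    """Plain unit-cost edit distance (edlib; used for fast screening)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def identity_bounds(a: str, b: str) -> Tuple[float, float]:
    """Sound lower/upper bounds on canonical identity from the edit
    distance alone, without the mismatch-minimising DP.

    With ``la <= lb`` and edit cost ``k``: mismatches range over
    ``[parity, k - (lb - la)]`` in steps of 2, hence matches range over
    ``[lb - k, (la + lb - k - parity) / 2]``.
    """
    la, lb = sorted((len(a), len(b)))
    k = edit_distance(a, b)
    parity = (k - (lb - la)) % 2
    lo = max(lb - k, 0) / la
    hi = min((la + lb - k - parity) // 2, la) / la
    return lo, hi


def global_alignment_path(query: str, target: str) -> List[Tuple[int, str]]:
    """Optimal unit-cost global alignment of ``query`` against ``target``
    as expanded CIGAR ops ``(length, op)`` with op in ``=XID``
    (``I`` consumes query only, ``D`` consumes target only)."""
    res = edlib.align(query, target, mode="NW", task="path")
    ops: List[Tuple[int, str]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def align_pair_to_reference(member: str, reference: str
                            ) -> Tuple[List[str], Dict[int, str]]:
    """Project ``member`` onto ``reference`` coordinates.

    Returns ``(per_position, insertions)`` where ``per_position[i]`` is the
    member symbol (or ``"-"``) at reference position ``i`` and
    ``insertions[slot]`` is the member run inserted before reference
    position ``slot`` (``slot == len(reference)`` appends at the end).
    """
    per_pos: List[str] = []
    insertions: Dict[int, str] = {}
    qi = ti = 0
    for length, op in global_alignment_path(member, reference):
        if op in "=X":
            per_pos.extend(member[qi:qi + length])
            qi += length
            ti += length
        elif op == "D":  # gap in member across reference positions
            per_pos.extend("-" * length)
            ti += length
        elif op == "I":  # member insertion between reference positions
            insertions[ti] = insertions.get(ti, "") + member[qi:qi + length]
            qi += length
        else:  # pragma: no cover - edlib emits only =XID in NW mode
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return per_pos, insertions


def star_align(seqs: Sequence[str], reference_index: int = 0) -> List[str]:
    """Star multiple alignment: every sequence aligned pairwise to the
    reference, columns merged on reference coordinates with member-specific
    insertions stacked (left-aligned, gap-padded).  Row order is preserved
    and all rows have equal length.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ref = seqs[reference_index]
    projected = []
    for s in seqs:
        if s == ref:
            projected.append((list(ref), {}))
        else:
            projected.append(align_pair_to_reference(s, ref))
    ins_len = [0] * (len(ref) + 1)
    for _, ins in projected:
        for slot, run in ins.items():
            ins_len[slot] = max(ins_len[slot], len(run))
    rows: List[str] = []
    for per_pos, ins in projected:
        parts: List[str] = []
        for slot in range(len(ref) + 1):
            if ins_len[slot]:
                run = ins.get(slot, "")
                parts.append(run.ljust(ins_len[slot], "-"))
            if slot < len(ref):
                parts.append(per_pos[slot])
        rows.append("".join(parts))
    assert len({len(r) for r in rows}) == 1
    return rows
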