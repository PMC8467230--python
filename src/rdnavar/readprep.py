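"""CCS-level quality filtering, dual-barcode demultiplexing, length filter.

Filters mirror the sequencing protocol: keep reads with at least five
subreads and predicted quality >= 0.99, assign reads to samples by their
terminal barcode pair tolerating up to three mismatches per barcode
(Hamming, no indels), and keep amplicons of 1000-2000 bp inclusive.
Demultiplexing tests both read orientations, trims the barcodes and
normalises assigned reads to the forward strand; reads matching zero or
more than one (sample, orientation) combination are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .records import SequenceRecord, revcomp


@dataclass(frozen=True)
class BarcodePair:
    sample: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValueError(f"sample {self.sample!r}: empty barcode")


def barcode_pairs_from_frame(df: pd.DataFrame) -> List[BarcodePair]:
    pairs = [BarcodePair(r.sample, r.fwd_barcode, r.rev_barcode)
             for r in df.itertuples(index=False)]
    combos = {(p.fwd, p.rev) for p in pairs}
    if len(combos) != len(pairs):
        raise ValueError("barcode combinations are not unique")
    return pairs


@dataclass
class DemuxResult:
    """Partition of the input reads produced by demultiplexing."""

    assigned: Dict[str, List[SequenceRecord]]
    unassigned: List[str] = field(default_factory=list)  # no pair matched
    ambiguous: List[str] = field(default_factory=list)   # >1 match

    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def ccs_filter(reads: Iterable[SequenceRecord], min_subreads: int = 5,
               min_rq: float = 0.99
               ) -> Tuple[List[SequenceRecord], List[SequenceRecord]]:
    """Keep reads with n_subreads >= min_subreads AND read_quality >=
    min_rq (both bounds inclusive); absent metadata fails the filter."""
    kept, discarded = [], []
    for r in reads:
        ok = (r.n_subreads is not None and r.read_quality is not None
              and r.n_subreads >= min_subreads and r.read_quality >= min_rq)
        (kept if ok else discarded).append(r)
    return kept, discarded


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_barcode(seq: str, barcode: str, max_mm: int, end: str = "5p"
                  ) -> Tuple[bool, int]:
    """Compare the terminal window of |barcode| bases against the barcode
    position-by-position; a read end matches iff mismatches <= max_mm."""
    if len(barcode) >= len(seq):
        raise ValueError("barcode must be shorter than the sequence")
    window = seq[:len(barcode)] if end == "5p" else seq[-len(barcode):]
    mm = hamming(window, barcode)
    return mm <= max_mm, mm


def _pair_matches(seq: str, pair: BarcodePair, max_mm: int) -> bool:
    ok_f, _ = match_barcode(seq, pair.fwd, max_mm, end="5p")
    if not ok_f:
        return False
    ok_r, _ = match_barcode(seq, revcomp(pair.rev), max_mm, end="3p")
    return ok_r


def demultiplex(reads: Iterable[SequenceRecord],
                barcode_map: Sequence[BarcodePair],
                max_mm: int = 3) -> DemuxResult:
    """Assign each read to the unique sample whose barcode pair matches in
    exactly one orientation; trim barcodes and orient assigned reads
    forward.  Multi-hit reads are conservative discards (tag-switching
    guard)."""
    if not barcode_map:
        raise ValueError("barcode map is empty")
    result = DemuxResult(assigned={p.sample: [] for p in barcode_map})
    for read in reads:
        hits: List[Tuple[BarcodePair, str]] = []
        rc = revcomp(read.seq)
        for pair in barcode_map:
            for orient, seq in (("fwd", read.seq), ("rev", rc)):
                if _pair_matches(seq, pair, max_mm):
                    hits.append((pair, orient))
        if len(hits) != 1:
            (result.unassigned if not hits else result.ambiguous).append(read.id)
            continue
        pair, orient = hits[0]
        seq = read.seq if orient == "fwd" else rc
        trimmed = seq[len(pair.fwd):len(seq) - len(pair.rev)]
        result.assigned[pair.sample].append(
            replace(read, seq=trimmed, sample=pair.sample))
    return result


def length_filter(reads: Iterable[SequenceRecord], min_len: int = 1000,
                  max_len: int = 2000
                  ) -> Tuple[List[SequenceRecord], List[SequenceRecord]]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds)."""
    kept, discarded = [], []
    for r in reads:
        (kept if min_len <= len(r.seq) <= max_len else discarded).append(r)
    return kept, discarded
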