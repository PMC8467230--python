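"""Cleaving full-length amplicons into ITS and D1-D2 LSU parts.

The cut point is the binding site of the ITS4 primer: ITS4 primes the
reverse strand, so its binding site on the forward strand is the primer's
reverse complement, located between the 5.8S/ITS2 block and the LSU
domains.  The best (minimum-mismatch, leftmost on ties) site within the
mismatch budget is removed and the flanks become the ITS and LSU parts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .records import SequenceRecord, revcomp


@dataclass(frozen=True)
class SplitRead:
    """One amplicon cleaved at the primer site (0-based half-open)."""

    read_id: str
    its_part: str
    lsu_part: str
    site_start: int
    site_end: int
    mismatches: int


def locate_primer(seq: str, primer: str, max_mm: int = 3
                  ) -> Optional[Tuple[int, int]]:
    """Best match of the primer's binding site (revcomp of the primer) on
    the forward strand: scans every offset, returns (start, mismatches) of
    the minimum-mismatch site (leftmost on ties), or None if the best
    exceeds ``max_mm``."""
    site = revcomp(primer)
    if len(site) >= len(seq):
        raise ValueError("primer must be shorter than the sequence")
    sv = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    pv = np.frombuffer(site.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(sv, len(pv))
    mism = (windows != pv).sum(axis=1)
    start = int(mism.argmin())            # argmin is leftmost on ties
    best = int(mism[start])
    if best > max_mm:
        return None
    return start, best


def split_amplicon(read: SequenceRecord, primer: str, max_mm: int = 3
                   ) -> Optional[SplitRead]:
    """Cleave an orientation-normalised amplicon at the primer site.

    The matched window is excluded from both parts.  Returns None when no
    site is found within the budget; empty parts are legal here and are
    routed to per-region discards by the pipeline.
    """
    hit = locate_primer(read.seq, primer, max_mm)
    if hit is None:
        return None
    start, mm = hit
    end = start + len(primer)
    return SplitRead(read_id=read.id, its_part=read.seq[:start],
                     lsu_part=read.seq[end:], site_start=start,
                     site_end=end, mismatches=mm)
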