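"""Core domain records shared by every pipeline stage.

A :class:`SequenceRecord` is a named DNA sequence with the optional
CCS-level metadata the quality filter consumes (number of subreads,
predicted read quality), and :class:`PipelineConfig` collects every
threshold the pipeline applies, with the protocol defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

#: Standard ITS4 primer (reverse primer, 5'->3'), White et al.
ITS4_PRIMER = "TCCTCCGCTTATTGATATGC"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A nucleotide sequence plus optional per-read CCS metadata.

    ``n_subreads`` and ``read_quality`` mirror the ``np=``/``rq=`` tokens
    of CCS read headers; ``sample`` is filled in at demultiplexing.
    """

    id: str
    seq: str
    n_subreads: Optional[int] = None
    read_quality: Optional[float] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        if self.read_quality is not None and not 0.0 <= self.read_quality <= 1.0:
            raise ValueError(
                f"record {self.id!r}: read_quality {self.read_quality} outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=revcomp(self.seq))


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the full amplicon pipeline.

    Defaults follow the CCS amplicon protocol: at least five subreads and
    predicted accuracy >= 0.99 per read, at most three barcode mismatches,
    amplicon length 1000-2000 bp (inclusive), greedy clustering at 97%
    identity, and a minimum spanning network with epsilon = 0.
    """

    min_subreads: int = 5
    min_read_quality: float = 0.99
    max_barcode_mismatches: int = 3
    min_len: int = 1000
    max_len: int = 2000
    cluster_identity: float = 0.97
    epsilon: int = 0
    primer_its4: str = ITS4_PRIMER
    max_primer_mismatches: int = 3
    rng_seed: int = 0
    # identity denominator: "shorter" (clustering-tool convention) or "alignment"
    identity_denominator: str = "shorter"

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        for name in ("min_subreads", "max_barcode_mismatches", "min_len",
                     "max_len", "epsilon", "max_primer_mismatches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.identity_denominator not in ("shorter", "alignment"):
            raise ValueError("identity_denominator must be 'shorter' or 'alignment'")
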