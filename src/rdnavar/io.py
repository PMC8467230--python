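"""Reading and writing the pipeline's file formats.

Sequence files are FASTA/FASTQ (Biopython ``SeqIO`` underneath).  Per-read
CCS metadata travels in the header as ``np=<int> rq=<float>`` key=value
tokens, mirroring PacBio CCS header conventions; barcode maps and all
result tables are tab-separated with a header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .records import SequenceRecord


def _parse_tokens(description: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for tok in description.split()[1:]:  # first token is the id itself
        if "=" in tok:
            key, val = tok.split("=", 1)
            out[key] = val
    return out


def _metadata_suffix(rec: SequenceRecord) -> str:
    parts = []
    if rec.n_subreads is not None:
        parts.append(f"np={rec.n_subreads}")
    if rec.read_quality is not None:
        parts.append(f"rq={rec.read_quality:.6g}")
    if rec.sample is not None:
        parts.append(f"sample={rec.sample}")
    return (" " + " ".join(parts)) if parts else ""


def read_fastx(path: str, format: Optional[str] = None) -> List[SequenceRecord]:
    """Read a FASTA or FASTQ file into :class:`SequenceRecord` objects.

    ``format`` defaults from the file extension.  Sequences are uppercased;
    FASTQ per-base qualities are ignored (the scalar ``rq=`` header token
    is the read-quality channel).  An empty file yields an empty list.
    """
    fmt = format or _infer_format(path)
    records: List[SequenceRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(path, fmt)):
            tokens = _parse_tokens(rec.description)
            np_tok = tokens.get("np")
            rq_tok = tokens.get("rq")
            records.append(SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                n_subreads=int(np_tok) if np_tok is not None else None,
                read_quality=float(rq_tok) if rq_tok is not None else None,
                sample=tokens.get("sample"),
            ))
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
        ) from exc
    return records


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def write_fastx(records: Iterable[SequenceRecord], path: str,
                format: Optional[str] = None) -> None:
    """Write records as FASTA or FASTQ; metadata goes into header tokens.

    FASTQ output carries a flat placeholder quality string (the scalar
    ``rq`` token is authoritative).
    """
    fmt = format or _infer_format(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id + _metadata_suffix(rec)
            if fmt == "fasta":
                fh.write(f">{header}\n{rec.seq}\n")
            else:
                fh.write(f"@{header}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


def read_barcode_map(path: str) -> pd.DataFrame:
    """Barcode map TSV with columns ``sample``, ``fwd_barcode``,
    ``rev_barcode``; (fwd, rev) combinations must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "fwd_barcode", "rev_barcode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: barcode map missing columns {sorted(missing)}")
    if df.duplicated(["fwd_barcode", "rev_barcode"]).any():
        raise ValueError(f"{path}: duplicate barcode combinations")
    return df


def write_barcode_map(rows: Sequence[Tuple[str, str, str]], path: str) -> None:
    pd.DataFrame(rows, columns=["sample", "fwd_barcode", "rev_barcode"]).to_csv(
        path, sep="\t", index=False)


@dataclass(frozen=True)
class ReferenceRecord:
    """A curated (Sanger) reference sequence for one region of one strain."""

    id: str
    species: str
    region: str            # "ITS" or "LSU"
    seq: str
    sample: Optional[str] = None  # source strain, when known


def read_references(path: str) -> List[ReferenceRecord]:
    """Reference FASTA with headers
    ``>ACCESSION species=<name> region=<ITS|LSU> [sample=<strain>]``."""
    refs: List[ReferenceRecord] = []
    for rec in SeqIO.parse(path, "fasta"):
        tokens = _parse_tokens(rec.description)
        if "species" not in tokens or "region" not in tokens:
            raise ValueError(
                f"{path}: reference {rec.id!r} lacks species=/region= tokens")
        refs.append(ReferenceRecord(
            id=rec.id,
            species=tokens["species"].replace("_", " "),
            region=tokens["region"],
            seq=str(rec.seq).upper(),
            sample=tokens.get("sample"),
        ))
    return refs


def write_references(refs: Iterable[ReferenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in refs:
            sample = f" sample={r.sample}" if r.sample else ""
            fh.write(f">{r.id} species={r.species.replace(' ', '_')}"
                     f" region={r.region}{sample}\n{r.seq}\n")


def write_table(df: pd.DataFrame, path: str) -> None:
    """All result tables are TSV with a header row; missing cells render
    as ``-`` (matching the published table convention)."""
    df.to_csv(path, sep="\t", index=False, na_rep="-")
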