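"""Synthetic tagged-amplicon datasets with known intragenomic structure.

The generator emulates multi-copy fungal rDNA amplicons (whole ITS plus
the D1-D2 LSU domains, ~1.5 kb) sequenced as CCS-style long reads:

* a panel of species cassettes derived from one shared ancestor, with the
  internal reverse-primer binding site kept invariant so every amplicon
  can be cleaved into its ITS and LSU parts;
* per strain, one dominant rDNA haplotype plus a handful of minor variants
  at a configurable p-distance from the dominant copy — the "escaped
  concerted evolution" signal the pipeline is built to quantify;
* reads tagged with a dual barcode combination, randomly oriented, with
  i.i.d. substitution errors and per-read subread-count / read-quality
  metadata matching CCS conventions;
* a truth table assigning every read to its haplotype, so demultiplexing,
  clustering, consensus calling and the divergence summaries can all be
  checked against ground truth.

Defaults reproduce the study conditions the pipeline targets: dominant
clusters of 99-427 reads, minor clusters of 1-14 reads, minor-variant
divergence 0.01-0.09, subread depth averaging 33 with a floor of 5, and
per-base error rate 0.2% (read accuracy >= 99%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ReferenceRecord
from .records import ITS4_PRIMER, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesModel:
    """One species' rDNA cassette with annotated sub-regions.

    Spans are 0-based half-open on the cassette; the primer-site span holds
    the reverse complement of the ITS4 primer (its binding site on the
    forward strand) and is identical across all species of a panel.
    """

    name: str
    base_cassette: str
    its_span: Tuple[int, int]
    site_span: Tuple[int, int]
    lsu_span: Tuple[int, int]
    interspecific_divergence: float

    @property
    def its(self) -> str:
        return self.base_cassette[self.its_span[0]:self.its_span[1]]

    @property
    def lsu(self) -> str:
        return self.base_cassette[self.lsu_span[0]:self.lsu_span[1]]


@dataclass
class StrainModel:
    """A strain's rDNA copy pool: haplotypes with copy proportions.

    ``haplotypes[0]`` is the major variant (maximum proportion);
    ``divergences[i]`` is haplotype i's p-distance from the major."""

    strain_id: str
    species: SpeciesModel
    haplotypes: List[Tuple[str, float]]
    divergences: List[float]

    def __post_init__(self) -> None:
        props = [p for _, p in self.haplotypes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("copy proportions must sum to 1")
        if props[0] <= max(props[1:], default=0.0):
            raise ValueError("haplotype 0 must be the unique major variant")
        if self.divergences[0] != 0:
            raise ValueError("major haplotype has divergence 0 by definition")


@dataclass
class StrainTruth:
    """Ground truth for one strain's simulated reads."""

    strain_id: str
    haplotypes: List[str]
    expected_its: List[str]
    expected_lsu: List[str]
    read_to_hap: Dict[str, int] = field(default_factory=dict)
    read_orientation: Dict[str, str] = field(default_factory=dict)  # fwd/rev
    read_errors: Dict[str, int] = field(default_factory=dict)

    def counts(self) -> List[int]:
        out = [0] * len(self.haplotypes)
        for h in self.read_to_hap.values():
            out[h] += 1
        return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def mutate_haplotype(base: str, target_p_distance: float,
                     rng: np.random.Generator,
                     protected_spans: Sequence[Tuple[int, int]] = ()) -> str:
    """Substitution-only mutant of ``base`` at the requested p-distance.

    Exactly ``round(target * n_unprotected)`` sites outside the protected
    spans are substituted to a different base, so the realised p-distance
    is the rounded target over the full length.
    """
    if not 0.0 <= target_p_distance <= 0.2:
        raise ValueError("target_p_distance must be in [0, 0.2]")
    protected = np.zeros(len(base), dtype=bool)
    for s, e in protected_spans:
        protected[s:e] = True
    free = np.flatnonzero(~protected)
    n_sub = round(target_p_distance * len(free))
    if n_sub > len(free):
        raise ValueError("target divergence incompatible with protected spans")
    if n_sub == 0:
        return base
    sites = rng.choice(free, size=n_sub, replace=False)
    arr = np.frombuffer(base.encode("ascii"), dtype=np.uint8).copy()
    for pos in sites:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def build_species_panel(n_species: int, seed: int,
                        interspecific_divergence: float = 0.10,
                        its_len: int = 600, lsu_len: int = 850
                        ) -> List[SpeciesModel]:
    """Species cassettes as mutated copies of one random ancestor.

    The ITS4 binding site is protected from mutation and verified to occur
    exactly once per cassette; pairwise species p-distance is approximately
    twice the per-species divergence (independent mutations from the
    ancestor, minus coincidental overlaps).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    site = revcomp(ITS4_PRIMER)
    its_span = (0, its_len)
    site_span = (its_len, its_len + len(site))
    lsu_span = (its_len + len(site), its_len + len(site) + lsu_len)
    for _ in range(20):
        ancestor = random_dna(rng, its_len) + site + random_dna(rng, lsu_len)
        if ancestor.count(site) == 1:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not build an ancestor with a unique site")
    panel: List[SpeciesModel] = []
    for i in range(n_species):
        for _ in range(20):
            cassette = mutate_haplotype(ancestor, interspecific_divergence,
                                        rng, [site_span])
            if cassette.count(site) == 1:
                break
        else:
            raise RuntimeError(
                "divergence too high to preserve a unique primer site")
        panel.append(SpeciesModel(
            name=f"Species{i + 1:02d}", base_cassette=cassette,
            its_span=its_span, site_span=site_span, lsu_span=lsu_span,
            interspecific_divergence=interspecific_divergence))
    return panel


def make_strain(species: SpeciesModel, strain_id: str,
                minor_divergences: Sequence[float],
                read_counts: Sequence[int],
                rng: np.random.Generator,
                intraspecific_divergence: float = 0.0) -> StrainModel:
    """Build a strain: a major haplotype at ``intraspecific_divergence``
    from the species cassette, plus minors at the given p-distances from
    the major.  ``read_counts`` (major first) set the copy proportions."""
    if len(read_counts) != len(minor_divergences) + 1:
        raise ValueError("need one read count per haplotype (major first)")
    site = [species.site_span]
    major = mutate_haplotype(species.base_cassette, intraspecific_divergence,
                             rng, site)
    haps = [major] + [mutate_haplotype(major, d, rng, site)
                      for d in minor_divergences]
    total = sum(read_counts)
    props = [c / total for c in read_counts]
    return StrainModel(strain_id=strain_id, species=species,
                       haplotypes=list(zip(haps, props)),
                       divergences=[0.0, *minor_divergences])


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator
                  ) -> Tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), len(hits)


def simulate_strain_reads(strain: StrainModel, n_dominant: int,
                          minor_counts: Sequence[int],
                          barcodes: Tuple[str, str],
                          rng: np.random.Generator,
                          error_rate: float = 0.002,
                          mean_subreads: float = 33.0,
                          min_subreads: int = 5,
                          ) -> Tuple[List[SequenceRecord], StrainTruth]:
    """Simulate CCS-level reads for one strain.

    Each read is ``fwd_barcode + haplotype-with-errors +
    revcomp(rev_barcode)``, reverse-complemented with probability 0.5.
    Subread counts are ``min_subreads + Poisson(mean - min)``; read quality
    is one minus the realised per-base error fraction.
    """
    counts = [n_dominant, *minor_counts]
    if len(counts) != len(strain.haplotypes):
        raise ValueError("need one read count per haplotype")
    if sum(counts) <= 0:
        raise ValueError("zero total reads")
    fwd, rev = barcodes
    sp = strain.species
    truth = StrainTruth(
        strain_id=strain.strain_id,
        haplotypes=[h for h, _ in strain.haplotypes],
        expected_its=[h[sp.its_span[0]:sp.its_span[1]]
                      for h, _ in strain.haplotypes],
        expected_lsu=[h[sp.lsu_span[0]:sp.lsu_span[1]]
                      for h, _ in strain.haplotypes],
    )
    reads: List[SequenceRecord] = []
    serial = 0
    for hap_idx, n_reads in enumerate(counts):
        template = strain.haplotypes[hap_idx][0]
        for _ in range(n_reads):
            serial += 1
            read_id = f"{strain.strain_id}/{serial}/ccs"
            insert, n_err = _apply_errors(template, error_rate, rng)
            tagged = fwd + insert + revcomp(rev)
            orient = "rev" if rng.random() < 0.5 else "fwd"
            if orient == "rev":
                tagged = revcomp(tagged)
            n_sub = min_subreads + int(rng.poisson(
                max(mean_subreads - min_subreads, 0.0)))
            rq = 1.0 - n_err / len(template)
            reads.append(SequenceRecord(id=read_id, seq=tagged,
                                        n_subreads=n_sub, read_quality=rq))
            truth.read_to_hap[read_id] = hap_idx
            truth.read_orientation[read_id] = orient
            truth.read_errors[read_id] = n_err
    return reads, truth


def generate_barcode_pairs(n: int, rng: np.random.Generator,
                           length: int = 16, min_dist: int = 8
                           ) -> List[Tuple[str, str]]:
    """Random barcode pairs whose codes are mutually separated by at least
    ``min_dist`` Hamming distance (across the pooled fwd+rev sets)."""
    pool: List[np.ndarray] = []
    for _ in range(200 * n):
        cand = rng.choice(_BASES, size=length)
        if all(int((cand != c).sum()) >= min_dist for c in pool):
            pool.append(cand)
        if len(pool) == 2 * n:
            break
    else:
        raise RuntimeError("could not generate enough separated barcodes")
    codes = [c.tobytes().decode("ascii") for c in pool]
    return [(codes[2 * i], codes[2 * i + 1]) for i in range(n)]


@dataclass
class StudyConfig:
    """Conditions of the simulated study (defaults = target conditions)."""

    n_species: int = 9
    strains_per_species: int = 2
    interspecific_divergence: float = 0.10
    intraspecific_divergence: float = 0.003
    minor_count_range: Tuple[int, int] = (0, 3)       # minors per strain
    minor_divergence_range: Tuple[float, float] = (0.01, 0.09)
    dominant_reads_range: Tuple[int, int] = (99, 427)
    minor_reads_range: Tuple[int, int] = (1, 14)
    error_rate: float = 0.002
    mean_subreads: float = 33.0
    min_subreads: int = 5
    barcode_length: int = 16
    barcode_min_dist: int = 8
    its_len: int = 600
    lsu_len: int = 850
    seed: int = 0


@dataclass
class StudyData:
    """A full simulated study: reads, barcode map, references, truth."""

    config: StudyConfig
    panel: List[SpeciesModel]
    strains: List[StrainModel]
    barcode_map: pd.DataFrame           # sample, fwd_barcode, rev_barcode
    reads: List[SequenceRecord]         # pooled, shuffled
    truths: Dict[str, StrainTruth]      # by strain id
    references: List[ReferenceRecord]   # per-strain Sanger-style refs
    species_of: Dict[str, str]          # strain id -> species name

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths.values():
            for rid, h in t.read_to_hap.items():
                rows.append((rid, t.strain_id, h, t.read_orientation[rid],
                             t.read_errors[rid]))
        return pd.DataFrame(
            rows, columns=["read_id", "sample", "hap_index", "orientation",
                           "n_errors"])


def write_study(study: "StudyData", outdir: str) -> None:
    """Write a simulated study to disk: reads (FASTQ with np=/rq= header
    metadata), barcode map TSV, per-strain references FASTA, per-read
    truth TSV and the true haplotype pool FASTA."""
    import os

    from .io import write_fastx, write_references, write_table

    os.makedirs(outdir, exist_ok=True)
    write_fastx(study.reads, os.path.join(outdir, "reads.fastq"))
    study.barcode_map.to_csv(os.path.join(outdir, "barcodes.tsv"),
                             sep="\t", index=False)
    write_references(study.references, os.path.join(outdir,
                                                    "references.fasta"))
    write_table(study.truth_frame(), os.path.join(outdir, "truth.tsv"))
    haps = [SequenceRecord(f"{t.strain_id}/hap{i}", h)
            for t in study.truths.values()
            for i, h in enumerate(t.haplotypes)]
    write_fastx(haps, os.path.join(outdir, "true_haplotypes.fasta"))


def simulate_study(config: StudyConfig = StudyConfig()) -> StudyData:
    """Simulate the full multi-species study the pipeline is run on."""
    rng = np.random.default_rng(config.seed)
    panel = build_species_panel(
        config.n_species, seed=int(rng.integers(2**31)),
        interspecific_divergence=config.interspecific_divergence,
        its_len=config.its_len, lsu_len=config.lsu_len)
    n_strains = config.n_species * config.strains_per_species
    pairs = generate_barcode_pairs(n_strains, rng,
                                   length=config.barcode_length,
                                   min_dist=config.barcode_min_dist)
    strains: List[StrainModel] = []
    reads: List[SequenceRecord] = []
    truths: Dict[str, StrainTruth] = {}
    references: List[ReferenceRecord] = []
    species_of: Dict[str, str] = {}
    bc_rows = []
    idx = 0
    for sp in panel:
        for j in range(config.strains_per_species):
            strain_id = f"{sp.name}-{chr(65 + j)}"
            n_minor = int(rng.integers(config.minor_count_range[0],
                                       config.minor_count_range[1] + 1))
            divs = sorted(rng.uniform(*config.minor_divergence_range,
                                      size=n_minor).tolist())
            n_dom = int(rng.integers(config.dominant_reads_range[0],
                                     config.dominant_reads_range[1] + 1))
            minors = [int(rng.integers(config.minor_reads_range[0],
                                       config.minor_reads_range[1] + 1))
                      for _ in range(n_minor)]
            strain = make_strain(
                sp, strain_id, divs, [n_dom, *minors], rng,
                intraspecific_divergence=config.intraspecific_divergence)
            bc = pairs[idx]
            idx += 1
            recs, truth = simulate_strain_reads(
                strain, n_dom, minors, bc, rng,
                error_rate=config.error_rate,
                mean_subreads=config.mean_subreads,
                min_subreads=config.min_subreads)
            strains.append(strain)
            reads.extend(recs)
            truths[strain_id] = truth
            species_of[strain_id] = sp.name
            bc_rows.append((strain_id, bc[0], bc[1]))
            # Sanger-style references: the major haplotype's cleaved regions
            acc = f"SAN{idx:05d}"
            references.append(ReferenceRecord(
                id=f"{acc}-ITS", species=sp.name, region="ITS",
                seq=truth.expected_its[0], sample=strain_id))
            references.append(ReferenceRecord(
                id=f"{acc}-LSU", species=sp.name, region="LSU",
                seq=truth.expected_lsu[0], sample=strain_id))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    barcode_map = pd.DataFrame(
        bc_rows, columns=["sample", "fwd_barcode", "rev_barcode"])
    return StudyData(config=config, panel=panel, strains=strains,
                     barcode_map=barcode_map, reads=reads, truths=truths,
                     references=references, species_of=species_of)
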