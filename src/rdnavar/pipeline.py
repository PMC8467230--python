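"""End-to-end pipeline: CCS filter -> demultiplex -> length filter ->
region cleave -> cluster -> consensus -> divergence, haplotype networks,
classification.

Every stage's keep/discard counts are logged so the partition invariant
(bins plus discards equal the input) is checkable from the run log alone.
All tables are TSV; all sequence outputs are FASTA with ``n_reads``
provenance in consensus headers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import cluster as cl
from . import distance as dist
from . import identify as ident
from . import network as net
from . import readprep, regions
from .io import (ReferenceRecord, read_barcode_map, read_fastx,
                 read_references, write_table)
from .records import PipelineConfig, SequenceRecord

log = logging.getLogger("rdnavar")


@dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    config: PipelineConfig
    counts: Dict[str, int] = field(default_factory=dict)
    # sample -> region -> clusters / consensuses
    clusters: Dict[str, Dict[str, List[cl.Cluster]]] = field(default_factory=dict)
    consensuses: Dict[str, Dict[str, List[cl.ConsensusRecord]]] = field(
        default_factory=dict)
    divergence: Dict[str, pd.DataFrame] = field(default_factory=dict)
    haplotype_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    edge_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    classification: Optional[pd.DataFrame] = None

    def consensus_seqs(self, sample: str, region: str) -> List[str]:
        return [c.seq for c in self.consensuses[sample][region]]


def _split_sample(reads: Sequence[SequenceRecord], config: PipelineConfig
                  ) -> Tuple[Dict[str, List[SequenceRecord]], int, int]:
    """Cleave a sample's reads; returns per-region records plus counts of
    primer-not-found and empty-part discards."""
    out: Dict[str, List[SequenceRecord]] = {"ITS": [], "LSU": []}
    no_primer = empty_part = 0
    for r in reads:
        sp = regions.split_amplicon(r, config.primer_its4,
                                    config.max_primer_mismatches)
        if sp is None:
            no_primer += 1
            continue
        for region, part in (("ITS", sp.its_part), ("LSU", sp.lsu_part)):
            if part:
                out[region].append(SequenceRecord(
                    id=r.id, seq=part, n_subreads=r.n_subreads,
                    read_quality=r.read_quality, sample=r.sample))
            else:
                empty_part += 1
    return out, no_primer, empty_part


def run_pipeline(config: PipelineConfig,
                 reads: Sequence[SequenceRecord],
                 barcode_map: pd.DataFrame,
                 references: Optional[Sequence[ReferenceRecord]] = None,
                 outdir: Optional[str] = None) -> PipelineResult:
    """Run every stage on in-memory reads; write report files if
    ``outdir`` is given."""
    result = PipelineResult(config=config)
    counts = result.counts
    counts["input"] = len(reads)

    kept, low_q = readprep.ccs_filter(list(reads), config.min_subreads,
                                      config.min_read_quality)
    counts["low_quality"] = len(low_q)

    pairs = readprep.barcode_pairs_from_frame(barcode_map)
    demux = readprep.demultiplex(kept, pairs, config.max_barcode_mismatches)
    counts["unassigned"] = len(demux.unassigned)
    counts["ambiguous"] = len(demux.ambiguous)
    counts["assigned"] = demux.n_assigned()

    counts["length_filtered"] = 0
    counts["primer_not_found"] = 0
    counts["empty_region_part"] = 0
    samples = sorted(demux.assigned)
    per_sample_regions: Dict[str, Dict[str, List[SequenceRecord]]] = {}
    for sample in samples:
        in_len, out_len = readprep.length_filter(
            demux.assigned[sample], config.min_len, config.max_len)
        counts["length_filtered"] += len(out_len)
        split, no_primer, empty_part = _split_sample(in_len, config)
        counts["primer_not_found"] += no_primer
        counts["empty_region_part"] += empty_part
        per_sample_regions[sample] = split

    for sample in samples:
        result.clusters[sample] = {}
        result.consensuses[sample] = {}
        for region in ("ITS", "LSU"):
            recs = per_sample_regions[sample][region]
            if not recs:
                result.clusters[sample][region] = []
                result.consensuses[sample][region] = []
                continue
            clusters = cl.greedy_cluster(recs, config.cluster_identity,
                                         config.identity_denominator)
            result.clusters[sample][region] = clusters
            result.consensuses[sample][region] = cl.consensus_records(
                clusters, sample, region)
            log.info("%s/%s: %d reads -> %d clusters", sample, region,
                     len(recs), len(clusters))

    sanger_by_strain: Dict[str, Dict[str, List[str]]] = {"ITS": {}, "LSU": {}}
    origin_of: Dict[str, str] = {}
    if references:
        for ref in references:
            if ref.sample is not None:
                sanger_by_strain[ref.region].setdefault(
                    ref.sample, []).append(ref.seq)
                origin_of[ref.sample] = ref.species

    species_of = {s: origin_of.get(s, "unknown") for s in samples}
    for region in ("ITS", "LSU"):
        cons_by_strain = {s: result.consensus_seqs(s, region)
                          for s in samples
                          if result.consensuses[s][region]}
        if cons_by_strain:
            result.divergence[region] = dist.divergence_report(
                cons_by_strain, sanger_by_strain[region],
                {s: species_of[s] for s in cons_by_strain})

    # haplotype networks per species over the ITS region (consensuses plus
    # the species' references), mirroring the published analysis
    by_species: Dict[str, List[str]] = {}
    for s in samples:
        by_species.setdefault(species_of[s], []).append(s)
    ref_its = [r for r in (references or []) if r.region == "ITS"]
    for species, members in sorted(by_species.items()):
        seqs: List[str] = []
        tags: List[net.HaplotypeMember] = []
        for ref in ref_its:
            if ref.species == species:
                seqs.append(ref.seq)
                tags.append(net.HaplotypeMember(
                    ref.sample or ref.id, "SAN"))
        for s in members:
            for c in result.consensuses[s]["ITS"]:
                seqs.append(c.seq)
                tags.append(net.HaplotypeMember(c.id, "PacBio", c.n_reads))
        if not seqs:
            continue
        freq: Dict[str, int] = {}
        for q in seqs:
            freq[q] = freq.get(q, 0) + 1
        ref_idx = max(range(len(seqs)), key=lambda i: (freq[seqs[i]], -i))
        from .align import star_align
        rows = star_align(seqs, reference_index=ref_idx)
        haps = net.collapse_haplotypes(rows, tags)
        network = net.build_msn(haps, config.epsilon)
        hap_df, edge_df = net.network_report(network)
        result.haplotype_tables[species] = hap_df
        result.edge_tables[species] = edge_df

    if references:
        rows = []
        for s in samples:
            major = {region: (cl.select_major(result.consensuses[s][region])
                              if result.consensuses[s][region] else None)
                     for region in ("ITS", "LSU")}
            if major["ITS"] is None and major["LSU"] is None:
                continue
            res = ident.classify_combined(
                query_id=s,
                its_seq=major["ITS"].seq if major["ITS"] else None,
                lsu_seq=major["LSU"].seq if major["LSU"] else None,
                refs=list(references), origin=origin_of.get(s))
            rows.append({
                "strain": s, "origin": res.origin, "assigned": res.assigned,
                "distance": res.distance, "margin": res.margin,
                "flag": res.flag,
            })
        result.classification = pd.DataFrame(rows)

    if outdir:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for sample, by_region in result.consensuses.items():
        for region, cons in by_region.items():
            if not cons:
                continue
            base = os.path.join(outdir, f"{sample}_{region}")
            with open(base + "_consensus.fasta", "w") as fh:
                for c in cons:
                    fh.write(f">{c.id} region={c.region} "
                             f"n_reads={c.n_reads}\n{c.seq}\n")
            with open(base + "_clusters.fasta", "w") as fh:
                for k, clu in enumerate(result.clusters[sample][region], 1):
                    for m in clu.members:
                        fh.write(f">{m.id} cluster={k}\n{m.seq}\n")
            write_table(pd.DataFrame(
                [(c.id, c.n_reads) for c in cons],
                columns=["cluster", "n_reads"]),
                base + "_cluster_sizes.tsv")
    for region, df in result.divergence.items():
        write_table(df.round(4), os.path.join(outdir, f"divergence_{region}.tsv"))
    for species, df in result.haplotype_tables.items():
        safe = species.replace(" ", "_")
        write_table(df, os.path.join(outdir, f"haplotypes_{safe}.tsv"))
        write_table(result.edge_tables[species],
                    os.path.join(outdir, f"network_edges_{safe}.tsv"))
    if result.classification is not None:
        write_table(result.classification.round(4),
                    os.path.join(outdir, "classification.tsv"))
    write_table(pd.DataFrame(sorted(result.counts.items()),
                             columns=["stage", "count"]),
                os.path.join(outdir, "stage_counts.tsv"))


def run_pipeline_files(config: PipelineConfig, reads_path: str,
                       barcode_map_path: str,
                       references_path: Optional[str] = None,
                       outdir: str = "pipeline_out") -> PipelineResult:
    """File-based entry point used by the command line interface."""
    reads = read_fastx(reads_path)
    barcode_map = read_barcode_map(barcode_map_path)
    references = (read_references(references_path)
                  if references_path else None)
    return run_pipeline(config, reads, barcode_map, references, outdir)
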