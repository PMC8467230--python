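# Methods

## Problem and model

Nuclear ribosomal DNA occurs in tandem arrays of many copies per genome.
Concerted evolution normally homogenises these copies, but variants that
escape it persist as divergent minor copies, and long-read amplicon
sequencing (PacBio-style circular consensus sequencing, CCS) recovers all
of them at once. For fungal barcoding this cuts both ways: the dominant
variant identifies the species, while minor variants can sit closer to
another species' barcode than to their own. `rdnavar` implements the full
desk-side protocol for quantifying this intragenomic variation from
amplicons spanning the whole ITS region (ITS1–5.8S–ITS2) plus the D1–D2
domains of the LSU, and for testing how reliably species identification
survives it.

The pipeline stages, with their defaults:

1. **CCS quality filter** — keep reads with at least `min_subreads = 5`
   subreads and predicted read quality `rq >= 0.99` (both inclusive).
   Subread count and `rq` travel in FASTA/FASTQ headers as `np=<int>
   rq=<float>` tokens, mirroring CCS header conventions.
2. **Dual-barcode demultiplexing** — each read is tested in both
   orientations against every sample's (forward, reverse) barcode pair;
   a barcode matches its terminal window by Hamming comparison with at
   most `max_barcode_mismatches = 3` mismatches *per barcode*. A read is
   assigned only if exactly one (sample, orientation) combination
   matches; multi-hit reads are discarded as potential tag-switching
   artefacts. Assigned reads are trimmed and normalised to the forward
   strand.
3. **Length filter** — keep amplicons of 1000–2000 bp, bounds inclusive.
4. **Region cleaving** — the ITS4 primer (`TCCTCCGCTTATTGATATGC`) primes
   the reverse strand between the ITS and LSU blocks, so its binding site
   on the forward strand is the primer's reverse complement. The
   minimum-mismatch site (leftmost on ties, budget
   `max_primer_mismatches = 3`) is located by exhaustive scan; the window
   itself is removed and the flanks become the ITS and LSU parts. An
   empty part discards the read for that region only.
5. **Greedy 97% clustering** — sequences sorted by decreasing length
   (ties by id) each join the first existing cluster whose
   *representative* they match at identity `>= cluster_identity = 0.97`,
   else found a new cluster — the greedy longest-first scheme of the
   standard identity-clustering tools, with identity defined as matching
   columns over the shorter sequence's length (the tools' documented
   convention; an alignment-length denominator is available as
   `identity_denominator = "alignment"`).
6. **Star alignment and majority-rule consensus** — cluster members are
   aligned pairwise to the representative and merged on representative
   coordinates with member insertions stacked; the per-column majority
   symbol wins, ties break toward the representative, gap-majority
   columns are deleted. Consensus ids number clusters by decreasing size
   (`<sample>-C1` is the largest); the max-read consensus is the **major
   variant**.
7. **Divergence summaries** — four averages of pairwise p-distance:
   intragenomic (consensus pairs within a strain), reference discrepancy
   (consensus x own reference), intraspecific by reference and by
   consensus (between-strain pairs within a species). The consensus-based
   intraspecific mean uses *all* consensuses, not majors only, because
   minor variants are precisely the signal that column exposes.
8. **Haplotype networks** — per species, ITS consensuses plus references
   are jointly star-aligned, identical rows collapse into haplotypes
   ranked by frequency, and a minimum spanning network is built on
   integer mutational distances (differing gap-free columns).
9. **Classification** — nearest-reference assignment by p-distance, per
   region or with both regions combined by length-weighted distance; a
   query assigned outside its origin species is flagged an outlier. A
   neighbour-joining tree over the p-distance matrix is available for
   visual QC (it replaces heavyweight likelihood/Bayesian phylogenetics,
   which are outside this package's scope — the identification criterion
   here is proximity to references, which nearest-distance captures
   directly).

## Alignment measures

Identity and p-distance both derive from a global pairwise alignment with
unit mismatch/gap costs. Optimal-cost alignments are not unique, so the
package fixes a canonical one: among minimum-cost alignments, the one
with the fewest gap columns — substitutions are preferred over indels at
equal cost, as an aligner with gap penalties would behave. This matters:
the opposite choice (fewest mismatches) lets free unit-cost gaps "hide"
substitutions near repeats and systematically deflates p-distance by
~10% at p ≈ 0.09. With the min-gap canonicalisation the measures are
symmetric, deterministic, and equal to a brute-force lexicographic DP on
every input:

* identity = match columns / shorter length,
* p-distance = mismatch columns / gap-free columns (pairwise deletion).

The implementation is a vectorised Needleman–Wunsch over values packed as
`cost * 2^20 + gap_columns`; a single lexicographic minimum drives both
objectives. Clustering decisions short-circuit through sound
edit-distance bounds (matches range over `[len_b - k,
(len_a + len_b - k - parity) / 2]` given edit distance `k`), so the full
DP runs only when the bounds straddle the threshold. Alignment *paths*
(needed only for gap placement in star alignment, where column counts are
irrelevant) come from edlib.

The p-distance is uncorrected by design; no JC/K2P correction is offered.
Distances here (≤ ~0.2) are far from saturation.

## Minimum spanning networks

For ε = 0 the network is exactly the union of all minimum spanning trees
of the complete mutational-distance graph. It is built by Kruskal with
distance classes: edges are processed in ascending distance classes, and
within a class an edge is admitted iff its endpoints lie in different
components *as frozen at the start of that class*; components merge only
after the class closes. For ε > 0 (the published tools leave this mode
loosely specified) each pair's admission threshold relaxes by ε distance
units beyond the class at which its endpoints first connect, which makes
the edge set grow monotonically with ε; ε = 0 is the contract-tested
mode and the default. Gap columns are unscored in mutational distance.
Haplotype collapsing uses exact aligned-row identity — conservative and
transitive; with the generator's substitution-only defaults it coincides
with ignoring gap columns.

## The synthetic-data generator

The generator (`rdnavar.sim`) emulates the study conditions the pipeline
targets, and its defaults *are* those conditions:

| parameter | default | rationale |
|---|---|---|
| species | 9, from one ancestor at divergence 0.10 | pairwise species p ≈ 0.2, a congeneric panel |
| strains per species | 2 | minimal intraspecific contrast |
| intraspecific divergence | 0.003 | reference-vs-reference p of a few parts per thousand |
| minors per strain | 0–3 at p 0.01–0.09 from the dominant copy | observed intragenomic range |
| dominant / minor reads | U[99, 427] / U[1, 14] | observed cluster-size ranges |
| subread depth | 5 + Poisson(28), floor 5 | mean ≈ 33, minimum 5 |
| error rate | 0.002/base, i.i.d. substitutions | CCS accuracy ≥ 99% after filtering |
| barcodes | 16-mers, pairwise Hamming ≥ 8, dual | unambiguous demultiplexing under a 3-mismatch budget |

Cassettes are ~1470 bp (600 bp ITS + 20 bp primer site + 850 bp LSU);
the primer site is protected from mutation and verified unique, so
cleaving is exact by construction. Mutation places exactly
`round(target x unprotected_length)` substitutions, so realised
divergences equal their targets to within one substitution. Reads are
`fwd_barcode + haplotype-with-errors + revcomp(rev_barcode)`, reverse
complemented with probability 0.5; `rq` is one minus the realised error
fraction; a per-read truth table records every assignment.

What the generator does **not** model: indels (an exactness choice —
lengths stay arithmetic; real CCS residual errors are indel-biased),
chimeras/tag switching (the demultiplexer's ambiguity discard is tested
with constructed collisions instead), PCR stochasticity, and per-base
quality variation beyond the scalar `rq`. Passing tests therefore
demonstrate correctness of the algorithms under substitution noise, not
robustness to indel-rich raw long reads.

## Numerical and degenerate-input choices

* All coordinates are 0-based half-open; orientation is normalised at
  demultiplexing, so downstream stages are single-strand.
* Boundary thresholds are inclusive everywhere (np = 5, rq = 0.99,
  lengths 1000 and 2000, 3 barcode mismatches all pass).
* Consensus ties break toward the representative; absent it, the
  lexicographically smallest tied symbol. Majority-rule consensus can
  correct independent errors only with ≥ 3 rows; a 2-read cluster's
  consensus equals its representative read, so singleton/2-read
  consensuses may retain sequencing errors (~2–3 per 1.5 kb at 0.2%).
  The divergence summaries tolerate this: reported intragenomic means
  stay within 0.005 of truth-based values.
* A minor variant within ~3% of the dominant copy cannot be separated at
  the 97% threshold and merges into the dominant cluster; near the
  threshold the outcome legitimately depends on which read founds the
  cluster (representatives are reads, carrying ~2 errors). Tests bracket
  expected cluster counts with a noise band of 6 x error-rate in
  identity units (two reads' errors plus Poisson spread).
* Zero reads surviving a stage is success with empty outputs, not an
  error; empty pair sets render as "-" in tables.
* Re-running with the same seed and inputs is byte-identical: every
  random draw flows from one `numpy` generator, and all orderings are
  explicit (length/id sort, founding order, frequency/first-seen).

## Problem sizes

The shipped analysis and the test suite run the full study at its native
size (9 x 2 strains, ~6000 reads, ~16 s for the complete pipeline on one
core). Unit and property tests use smaller instances chosen for exact
oracles: alignments ≤ 30 bp against a tuple DP, networks ≤ 7 haplotypes
against exhaustive spanning-tree enumeration, and reduced read counts
where only the mechanism (not the statistics) is under test.

## Known limitations

* Identity and p-distance use pairwise global alignment rather than one
  joint multiple alignment; at within-cluster divergences (≥ 97%
  identity) the column counts agree, but for distant pairs a multiple
  alignment could score columns differently.
* The greedy clustering reproduces the longest-first assignment rule,
  not any particular tool's word-filter heuristics; agreement with a
  specific external tool on borderline clusters is not guaranteed (nor
  stable between that tool's own versions).
* Combined-region classification weights regions by query length;
  a likelihood-based combination is out of scope.
* ε > 0 networks follow this package's definition above; only ε = 0 is
  cross-checked against an independent oracle.
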