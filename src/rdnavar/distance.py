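"""Uncorrected p-distances and the four divergence summary statistics.

p-distance is the fraction of mismatching columns among gap-free columns
("pairwise deletion") of the canonical global pairwise alignment — the
convention of the standard distance software when computing pairwise
distances.  The report assembles, per strain and per species:

* intragenomic variation: mean p over distinct consensus pairs within a
  strain (absent with fewer than two consensuses);
* reference discrepancy: mean p between a strain's consensuses and its
  own Sanger-style reference;
* intraspecific variation (Sanger): mean p between the references of
  different strains within a species;
* intraspecific variation (PacBio): mean p between consensuses of
  different strains within a species (all consensuses, not majors only —
  minor variants are the signal this column exists to expose).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import skbio

from . import align


def pairwise_p_distance(a: str, b: str) -> float:
    """Mismatch fraction over gap-free columns of the canonical global
    alignment of the pair; symmetric."""
    return align.edit_stats(a, b).p_distance


def p_distance_matrix(labels: Sequence[str], seqs: Sequence[str]
                      ) -> skbio.DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise p-distances."""
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pairwise_p_distance(seqs[i], seqs[j])
    return skbio.DistanceMatrix(mat, ids=list(labels))


def mean_pairset_distance(seqs_a: Sequence[str],
                          seqs_b: Optional[Sequence[str]] = None
                          ) -> Optional[float]:
    """Average p-distance over a pair set.

    Within one set (``seqs_b`` None): unordered distinct pairs.  Between
    two sets: the full cross product.  Returns None when the pair set is
    empty (rendered "-" in tables).
    """
    if seqs_b is None:
        pairs = list(combinations(seqs_a, 2))
    else:
        pairs = [(a, b) for a in seqs_a for b in seqs_b]
    if not pairs:
        return None
    return float(np.mean([pairwise_p_distance(a, b) for a, b in pairs]))


def divergence_report(consensuses_by_strain: Mapping[str, Sequence[str]],
                      sanger_by_strain: Mapping[str, Sequence[str]],
                      species_of: Mapping[str, str]) -> pd.DataFrame:
    """The four-column divergence table over all strains.

    Species-level intraspecific means (between-strain pairs only) are
    repeated on every row of the species; absent statistics are NaN
    (rendered "-" when written).
    """
    strains = list(consensuses_by_strain)
    by_species: Dict[str, List[str]] = {}
    for s in strains:
        by_species.setdefault(species_of[s], []).append(s)

    intraspecific_sanger: Dict[str, Optional[float]] = {}
    intraspecific_pacbio: Dict[str, Optional[float]] = {}
    for sp, members in by_species.items():
        san_pairs, pb_pairs = [], []
        for s1, s2 in combinations(members, 2):
            san_pairs.extend(
                (a, b) for a in sanger_by_strain.get(s1, [])
                for b in sanger_by_strain.get(s2, []))
            pb_pairs.extend(
                (a, b) for a in consensuses_by_strain[s1]
                for b in consensuses_by_strain[s2])
        intraspecific_sanger[sp] = (
            float(np.mean([pairwise_p_distance(a, b) for a, b in san_pairs]))
            if san_pairs else None)
        intraspecific_pacbio[sp] = (
            float(np.mean([pairwise_p_distance(a, b) for a, b in pb_pairs]))
            if pb_pairs else None)

    rows = []
    for s in strains:
        cons = list(consensuses_by_strain[s])
        sanger = list(sanger_by_strain.get(s, []))
        rows.append({
            "species": species_of[s],
            "strain": s,
            "intragenomic_pacbio": mean_pairset_distance(cons),
            "sanger_pacbio_discrepancy": (
                mean_pairset_distance(cons, sanger) if sanger else None),
            "intraspecific_sanger": intraspecific_sanger[species_of[s]],
            "intraspecific_pacbio": intraspecific_pacbio[species_of[s]],
        })
    df = pd.DataFrame(rows)
    for col in ("intragenomic_pacbio", "sanger_pacbio_discrepancy",
                "intraspecific_sanger", "intraspecific_pacbio"):
        df[col] = df[col].astype(float)  # None -> NaN, never object dtype
    return df
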