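"""Cross-species comparison of capped-peptide sets.

Exact conservation between mouse and human sets, pairwise global-alignment
similarity, and an average-linkage dendrogram over peptide sequences. The
dendrogram is a guide tree built from Needleman-Wunsch identity distances
(match +1, mismatch 0, gap -1; distance = 1 - matches/alignment_length);
it is a deliberately simple substitute for a full progressive-MSA
phylotree and is only meant to group homologous sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PeptidePair",
    "find_conserved",
    "pairwise_identity",
    "distance_matrix",
    "cluster_peptides",
]


@dataclass(frozen=True)
class PeptidePair:
    name_a: str
    name_b: str
    core_a: str
    core_b: str
    species_a: str
    species_b: str
    identity: float


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity fraction, alignment score) under NW global alignment.

    Identity = matched positions / alignment length, on the best-scoring
    alignment (first alignment for determinism).
    """
    if seq_a == seq_b:
        return 1.0, float(len(seq_a))
    aln = _aligner().align(seq_a, seq_b)[0]
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(*aln.aligned)
        for i in range(a1 - a0)
        if seq_a[a0 + i] == seq_b[b0 + i]
    )
    # alignment length = aligned columns + gap columns
    length = len(str(aln[0]))
    return matches / length, float(aln.score)


def find_conserved(set_a: Sequence, set_b: Sequence) -> list[PeptidePair]:
    """Pairs with identical core sequences across the two species sets.

    Inputs may be candidate objects (``core_sequence``/``species`` fields)
    or bare sequences.
    """
    def unpack(item, default_species):
        core = getattr(item, "core_sequence", item)
        name = getattr(item, "capped_notation", core)
        species = getattr(item, "species", "") or default_species
        return name, core, species

    pairs = []
    for ia in set_a:
        na, ca, sa = unpack(ia, "a")
        for ib in set_b:
            nb, cb, sb = unpack(ib, "b")
            if ca == cb:
                pairs.append(PeptidePair(na, nb, ca, cb, sa, sb, 1.0))
    return pairs


def distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric identity-distance matrix, d = 1 - identity, d(x,x)=0."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(sequences[i], sequences[j])
            d[i, j] = d[j, i] = 1.0 - ident
    return d


def cluster_peptides(
    peptides: Sequence[str], labels: Sequence[str] | None = None
) -> str:
    """Average-linkage guide tree over peptides, serialized as Newick.

    Peptides are sorted lexicographically before clustering so reruns are
    bit-identical regardless of input order; duplicate sequences (zero
    distance) are allowed.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides to cluster")
    if labels is None:
        labels = list(peptides)
    order = sorted(range(len(peptides)), key=lambda i: (peptides[i], labels[i]))
    seqs = [peptides[i] for i in order]
    labs = [labels[i] for i in order]
    d = distance_matrix(seqs)
    z = linkage(squareform(d, checks=False), method="average")

    def newick(node_id: int) -> str:
        if node_id < len(seqs):
            return labs[node_id].replace(" ", "_")
        row = z[node_id - len(seqs)]
        left, right, height = int(row[0]), int(row[1]), row[2]

        def branch(child: int) -> float:
            child_h = 0.0 if child < len(seqs) else z[child - len(seqs)][2]
            return max(height - child_h, 0.0) / 2

        return (
            f"({newick(left)}:{branch(left):.6f},"
            f"{newick(right)}:{branch(right):.6f})"
        )

    return newick(len(seqs) + len(z) - 1) + ";"
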