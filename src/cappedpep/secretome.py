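"""Secretome parsing and capped-peptide candidate prediction.

A "capped peptide" is a proteolytic fragment of a classically secreted
protein that carries an N-terminal pyroglutamate (cyclized Gln) and a
C-terminal amide. Candidates are read off the precursor sequence: a
C-terminal amidation site is marked by a Gly-dibasic tripeptide motif
(GKR or GRR; the Gly is the amide donor), and the peptide is the
inclusive span from an upstream Gln to the residue immediately preceding
that Gly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import AMBIGUOUS_RESIDUES, CANONICAL_RESIDUES

__all__ = [
    "ProteinRecord",
    "CappedPeptideCandidate",
    "read_fasta",
    "find_amidation_motifs",
    "predict_capped_peptides",
    "predict_proteome",
    "predictions_to_frame",
    "write_predictions",
]

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_GENE_FIELD = re.compile(r"GN=(\S+)")


@dataclass(frozen=True)
class ProteinRecord:
    """One secretome entry.

    ``signal_peptide_end`` is the 1-based index of the last signal-peptide
    residue when the annotation is available, else ``None``.
    """

    accession: str
    sequence: str
    gene: str | None = None
    species: str = ""
    signal_peptide_end: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES - AMBIGUOUS_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: unknown residue letters {sorted(bad)}"
            )

    @property
    def has_ambiguous_residues(self) -> bool:
        return bool(set(self.sequence) & AMBIGUOUS_RESIDUES)


@dataclass(frozen=True)
class CappedPeptideCandidate:
    """A predicted capped peptide with 1-based inclusive precursor coordinates.

    ``start`` indexes the Gln that cyclizes to pyroGlu; ``end`` the residue
    immediately preceding the motif glycine (the residue that ends up
    amidated). ``core_sequence`` is the unmodified span Q...end;
    ``capped_notation`` writes the mature chemical form with the leading Q
    replaced by pGlu.
    """

    precursor_accession: str
    start: int
    end: int
    core_sequence: str
    motif: str
    motif_position: int
    gene: str | None = None
    species: str = ""
    duplicate_core: bool = False

    def __post_init__(self) -> None:
        if not self.core_sequence:
            raise ValueError("core_sequence must be non-empty")
        if self.end != self.motif_position - 1:
            raise ValueError("end must abut the motif glycine")
        if self.motif not in ("GKR", "GRR"):
            raise ValueError(f"invalid motif {self.motif!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def capped_notation(self) -> str:
        # Gln (and Glu) cyclize to pyroglutamate; other N-terminal
        # residues (alternative prediction criteria) keep their letter
        head = self.core_sequence[0]
        prefix = "pGlu" if head in "QE" else head
        return f"{prefix}-{self.core_sequence[1:]}-NH2"


def _parse_header(description: str) -> tuple[str, str | None]:
    """Accession and optional gene from a FASTA header.

    Understands the UniProt ``sp|ACC|NAME ... GN=gene`` dialect; any other
    header yields its first whitespace-delimited token as the accession.
    """
    m = _UNIPROT_HEADER.match(description)
    acc = m.group("acc") if m else description.split()[0]
    g = _GENE_FIELD.search(description)
    return acc, (g.group(1) if g else None)


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a secretome FASTA into an ordered list of :class:`ProteinRecord`.

    Raises ``ValueError`` on duplicate accessions or entries with no
    sequence; sequence letters are uppercased.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        acc, gene = _parse_header(entry.description)
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=str(entry.seq).upper(),
                gene=gene,
                species=species,
            )
        )
    return records


def find_amidation_motifs(sequence: str) -> list[int]:
    """1-based positions of the G of every G[KR]R amidation motif.

    Overlapping occurrences are all reported; windows containing
    ambiguity letters never match.
    """
    out = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "G"
            and sequence[i + 1] in "KR"
            and sequence[i + 2] == "R"
        ):
            out.append(i + 1)
    return out


def predict_capped_peptides(
    record: ProteinRecord,
    max_length: int = 20,
    min_length: int = 2,
    nterm_residue: str = "Q",
    exclude_signal_peptide: bool = False,
) -> list[CappedPeptideCandidate]:
    """Enumerate capped-peptide candidates for one precursor.

    For every amidation motif, every ``nterm_residue`` whose distance to
    the motif glycine puts the candidate length (N-terminal residue
    through the pre-motif residue, inclusive) within
    ``[min_length, max_length]`` yields one candidate. Candidates whose
    span contains an ambiguity letter are dropped. With
    ``exclude_signal_peptide`` set, candidates overlapping an annotated
    signal peptide are dropped as well (off by default: real capped
    peptides can start only a few residues past the signal peptide).

    Output is sorted by (motif_position, start). When the same core
    sequence arises at several positions within one precursor, every
    occurrence is retained and flagged ``duplicate_core``.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if max_length < min_length:
        raise ValueError("max_length must be >= min_length")
    if len(nterm_residue) != 1 or nterm_residue not in CANONICAL_RESIDUES:
        raise ValueError(f"nterm_residue must be a canonical letter, got {nterm_residue!r}")

    seq = record.sequence
    candidates: list[CappedPeptideCandidate] = []
    for motif_pos in find_amidation_motifs(seq):
        lo = max(1, motif_pos - max_length)
        hi = motif_pos - min_length
        for q_pos in range(lo, hi + 1):
            if seq[q_pos - 1] != nterm_residue:
                continue
            core = seq[q_pos - 1 : motif_pos - 1]
            if set(core) & AMBIGUOUS_RESIDUES:
                continue
            if (
                exclude_signal_peptide
                and record.signal_peptide_end is not None
                and q_pos <= record.signal_peptide_end
            ):
                continue
            candidates.append(
                CappedPeptideCandidate(
                    precursor_accession=record.accession,
                    start=q_pos,
                    end=motif_pos - 1,
                    core_sequence=core,
                    motif=seq[motif_pos - 1 : motif_pos + 2],
                    motif_position=motif_pos,
                    gene=record.gene,
                    species=record.species,
                )
            )
    candidates.sort(key=lambda c: (c.motif_position, c.start))
    counts: dict[str, int] = {}
    for c in candidates:
        counts[c.core_sequence] = counts.get(c.core_sequence, 0) + 1
    return [
        CappedPeptideCandidate(
            **{**c.__dict__, "duplicate_core": counts[c.core_sequence] > 1}
        )
        for c in candidates
    ]


def predict_proteome(
    records: Iterable[ProteinRecord], **kwargs
) -> list[CappedPeptideCandidate]:
    """Run :func:`predict_capped_peptides` across a whole secretome."""
    out: list[CappedPeptideCandidate] = []
    for rec in records:
        out.extend(predict_capped_peptides(rec, **kwargs))
    return out


def predictions_to_frame(
    candidates: Sequence[CappedPeptideCandidate],
) -> pd.DataFrame:
    cols = [
        "accession",
        "gene",
        "start",
        "end",
        "core_sequence",
        "capped_notation",
        "length",
        "motif",
        "motif_position",
    ]
    rows = [
        (
            c.precursor_accession,
            c.gene,
            c.start,
            c.end,
            c.core_sequence,
            c.capped_notation,
            c.length,
            c.motif,
            c.motif_position,
        )
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=cols)


def write_predictions(
    candidates: Sequence[CappedPeptideCandidate], path: str | Path
) -> None:
    predictions_to_frame(candidates).to_csv(path, sep="\t", index=False)
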