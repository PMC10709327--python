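"""Peptide mass-spec chemistry: monoisotopic masses, ions, MRM transitions.

All masses are monoisotopic daltons. A capped peptide written
``pGlu-XXX-NH2`` is represented by its core sequence (starting with the
Gln that cyclizes) plus two modification deltas: pyroGlu-from-Gln
(-17.0265 Da, loss of ammonia) and C-terminal amide (-0.9840 Da, OH to
NH2). These two deltas sum to exactly minus one water, so a fully capped
peptide's neutral mass equals the bare sum of its residue masses — a
useful cross-check identity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import (
    AMMONIA_MASS,
    CARBAMIDOMETHYL_CYS_DELTA,
    C_AMIDE_DELTA,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    PYROGLU_FROM_GLN_DELTA,
    WATER_MASS,
)

__all__ = [
    "ModificationSet",
    "CAPPED_MODS",
    "PeptideIon",
    "FragmentIon",
    "MrmTransition",
    "peptide_mass",
    "ion_mz",
    "fragment_ions",
    "precursor_ion",
    "build_transition_list",
    "transitions_to_frame",
    "scramble_control",
]


@dataclass(frozen=True)
class ModificationSet:
    """Which terminal/fixed modifications apply to a peptide.

    ``carbamidomethyl_cys`` reflects iodoacetamide alkylation during
    sample preparation and is applied per cysteine; the terminal caps are
    applied once each.
    """

    pyroglu_from_gln: bool = True
    c_amide: bool = True
    carbamidomethyl_cys: bool = False
    custom_deltas: Mapping[str, float] = field(default_factory=dict)

    def terminal_delta(self) -> float:
        d = 0.0
        if self.pyroglu_from_gln:
            d += PYROGLU_FROM_GLN_DELTA
        if self.c_amide:
            d += C_AMIDE_DELTA
        d += sum(self.custom_deltas.values())
        return d


#: The standard capped-peptide form: pyroGlu + C-amide, no Cys alkylation.
CAPPED_MODS = ModificationSet()


@dataclass(frozen=True)
class PeptideIon:
    sequence: str
    mods: ModificationSet
    neutral_mass: float
    charge: int
    mz: float


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    charge: int
    mz: float

    @property
    def annotation(self) -> str:
        return f"{self.series}{self.index}{'+' * self.charge}"


@dataclass(frozen=True)
class MrmTransition:
    compound: str
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_annotation: str
    collision_energy: float | None = None


def _residue_masses(sequence: str) -> list[float]:
    masses = []
    for pos, aa in enumerate(sequence, start=1):
        try:
            masses.append(MONOISOTOPIC_RESIDUE_MASS[aa])
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos}"
            ) from None
    return masses


def peptide_mass(sequence: str, mods: ModificationSet = CAPPED_MODS) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    masses = _residue_masses(sequence)
    mass = sum(masses) + WATER_MASS + mods.terminal_delta()
    if mods.carbamidomethyl_cys:
        mass += CARBAMIDOMETHYL_CYS_DELTA * sequence.count("C")
    return mass


def ion_mz(neutral_mass: float, charge: int) -> float:
    """m/z of the [M+zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def precursor_ion(
    sequence: str, mods: ModificationSet = CAPPED_MODS, charge: int = 1
) -> PeptideIon:
    m = peptide_mass(sequence, mods)
    return PeptideIon(sequence, mods, m, charge, ion_mz(m, charge))


def fragment_ions(
    sequence: str,
    mods: ModificationSet = CAPPED_MODS,
    series: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """b/y fragment ions at charges 1..max_charge.

    b_i carries the N-terminal modifications (pyroGlu); y_i carries the
    C-terminal ones: for an amidated peptide the y-ion neutral ends in
    NH2, i.e. residue sum + ammonia instead of residue sum + water.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 residues to fragment")
    bad = set(series) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported series {sorted(bad)}; only b and y")
    masses = _residue_masses(sequence)
    nterm_delta = PYROGLU_FROM_GLN_DELTA if mods.pyroglu_from_gln else 0.0
    cterm_mass = AMMONIA_MASS if mods.c_amide else WATER_MASS
    if mods.carbamidomethyl_cys:
        masses = [
            m + (CARBAMIDOMETHYL_CYS_DELTA if aa == "C" else 0.0)
            for m, aa in zip(masses, sequence)
        ]

    out: list[FragmentIon] = []
    prefix = 0.0
    b_neutral = []  # neutral b fragment masses (acylium + nothing extra)
    for m in masses[:-1]:
        prefix += m
        b_neutral.append(prefix + nterm_delta)
    suffix = 0.0
    y_neutral = []
    for m in reversed(masses[1:]):
        suffix += m
        y_neutral.append(suffix + cterm_mass)

    for z in range(1, max_charge + 1):
        if "b" in series:
            for i, m in enumerate(b_neutral, start=1):
                out.append(FragmentIon("b", i, z, (m + z * PROTON_MASS) / z))
        if "y" in series:
            for i, m in enumerate(y_neutral, start=1):
                out.append(FragmentIon("y", i, z, (m + z * PROTON_MASS) / z))
    return out


def _best_fragment_from_spectrum(
    frags: list[FragmentIon],
    spectrum: Sequence[tuple[float, float]],
    tol_da: float,
) -> FragmentIon | None:
    best: FragmentIon | None = None
    best_intensity = -1.0
    for f in frags:
        for mz, inten in spectrum:
            if abs(mz - f.mz) <= tol_da and inten > best_intensity:
                best, best_intensity = f, inten
    return best


def build_transition_list(
    candidates: Iterable,
    msms_reference: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    mods: ModificationSet = CAPPED_MODS,
    precursor_charge: int = 1,
    product_mz_floor: float = 200.0,
    spectrum_tol_da: float = 0.5,
) -> tuple[list[MrmTransition], list[str]]:
    """One MRM transition per candidate.

    When a reference MS/MS spectrum for the compound is available, the
    product ion is the theoretical b/y fragment matching the tallest
    spectrum peak; otherwise the highest-m/z b/y fragment above
    ``product_mz_floor``. Candidates with no usable fragment are returned
    in the flagged list instead of the transition list.

    ``candidates`` may be CappedPeptideCandidate objects or bare core
    sequences.
    """
    transitions: list[MrmTransition] = []
    flagged: list[str] = []
    for cand in candidates:
        core = getattr(cand, "core_sequence", cand)
        compound = getattr(cand, "capped_notation", f"pGlu-{core[1:]}-NH2")
        parent = precursor_ion(core, mods, precursor_charge)
        frags = [f for f in fragment_ions(core, mods) if f.mz >= product_mz_floor]
        chosen: FragmentIon | None = None
        if msms_reference and compound in msms_reference:
            chosen = _best_fragment_from_spectrum(
                frags, msms_reference[compound], spectrum_tol_da
            )
        if chosen is None:
            chosen = max(frags, key=lambda f: f.mz, default=None)
        if chosen is None:
            flagged.append(compound)
            continue
        transitions.append(
            MrmTransition(
                compound=compound,
                precursor_mz=parent.mz,
                precursor_charge=precursor_charge,
                product_mz=chosen.mz,
                product_annotation=chosen.annotation,
            )
        )
    return transitions, flagged


def transitions_to_frame(transitions: Sequence[MrmTransition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.compound,
                t.precursor_mz,
                t.precursor_charge,
                t.product_mz,
                t.product_annotation,
                t.collision_energy,
            )
            for t in transitions
        ],
        columns=[
            "compound",
            "precursor_mz",
            "precursor_charge",
            "product_mz",
            "product_annotation",
            "collision_energy",
        ],
    )


def scramble_control(core_sequence: str, seed: int) -> str:
    """Sequence-scrambled control with identical composition, Q fixed first.

    The intervening residues are permuted with a seeded RNG; when any
    distinct permutation exists the output differs from the input.
    """
    if not core_sequence.startswith("Q"):
        raise ValueError("core must begin with Q")
    if len(core_sequence) < 3:
        raise ValueError("nothing to scramble in a core shorter than 3")
    body = list(core_sequence[1:])
    rng = random.Random(seed)
    if len(set(body)) == 1:
        return core_sequence
    for _ in range(1000):
        perm = body[:]
        rng.shuffle(perm)
        if perm != body:
            return "Q" + "".join(perm)
    return core_sequence  # unreachable for heterogeneous bodies
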