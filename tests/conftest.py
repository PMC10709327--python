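import random

import pytest


@pytest.fixture
def toy_fasta(tmp_path):
    """Two-entry FASTA: one UniProt-dialect header, one plain."""
    p = tmp_path / "toy.fasta"
    p.write_text(">sp|P1|A\nMQAGKRA\n>P2\nMAAA\n")
    return p


@pytest.fixture
def rng():
    return random.Random(20240901)


def brute_force_candidates(seq, max_length=20, min_length=2, nterm="Q"):
    """Independent triple-loop enumeration of (Q, motif) candidate pairs.

    Returns (start, end, motif_position) 1-based tuples, sorted the same
    way the predictor sorts. Deliberately naive: scans every window.
    """
    out = []
    for g in range(1, len(seq) + 1):  # candidate motif position
        if seq[g - 1 : g + 2] not in ("GKR", "GRR"):
            continue
        for q in range(1, g):  # candidate start
            if seq[q - 1] != nterm:
                continue
            length = g - q
            if not (min_length <= length <= max_length):
                continue
            core = seq[q - 1 : g - 1]
            if any(c in "BZXUO" for c in core):
                continue
            out.append((q, g - 1, g))
    return sorted(out, key=lambda t: (t[2], t[0]))
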