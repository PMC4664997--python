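"""Small shared sequence utilities (no external format logic here)."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNRYKMSWacgtn", "TGCANYRMKSWtgcan")

# transition partner for each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in PURINES) == (b in PURINES))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of an upper-cased sequence."""
    return np.frombuffer(seq.upper().encode(), dtype="S1")


def cpg_mask(seq: str) -> np.ndarray:
    """Boolean mask marking both positions of every CpG dinucleotide."""
    a = seq_to_array(seq)
    mask = np.zeros(len(a), dtype=bool)
    if len(a) >= 2:
        cg = (a[:-1] == b"C") & (a[1:] == b"G")
        mask[:-1] |= cg
        mask[1:] |= cg
    return mask


def n_runs(seq: str):
    """Intervals (0-based half-open) of runs of N."""
    runs = []
    start = None
    for i, c in enumerate(seq.upper()):
        if c == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs
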