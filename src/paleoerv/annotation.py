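"""Per-locus annotation: target-site duplications, primer-binding sites,
and frameshift-aware reconstruction of retroviral proteins ("puteins").

A retroviral integration duplicates 4-6 bp of host sequence on either side
of the element (the TSD); reverse transcription is primed by a host tRNA
whose 3' end anneals just inside the 5' LTR (the PBS).  Both are detected
here by exact/near-exact string scans.  Decayed reading frames are repaired
by a dynamic program that aligns the nucleotide sequence against a reference
protein while allowing penalised frame transitions, yielding the putein,
the number of corrected frameshifts, and percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._seq import revcomp
from .simulate import load_trna_library

__all__ = [
    "TsdCall",
    "PbsCall",
    "Putein",
    "detect_tsd",
    "detect_pbs",
    "reconstruct_putein",
]


@dataclass(frozen=True)
class TsdCall:
    tsd_seq: Optional[str]
    left_interval: Optional[tuple[int, int]] = None
    right_interval: Optional[tuple[int, int]] = None
    determinable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.tsd_seq is not None and len(self.tsd_seq) not in range(3, 8):
            raise ValueError("implausible TSD length")


@dataclass(frozen=True)
class PbsCall:
    trna_name: str
    match_length: int
    mismatches: int
    interval: tuple[int, int]  # on the locus sequence


@dataclass(frozen=True)
class Putein:
    gene: str
    sequence: str
    frameshift_count: int
    percent_identity: float
    interval: tuple[int, int]  # nt interval on the input sequence
    score: float = 0.0  # alignment score at the optimum

    def __post_init__(self) -> None:
        if self.frameshift_count < 0 or not (0 <= self.percent_identity <= 100):
            raise ValueError("invalid putein metrics")


# ---------------------------------------------------------------------------
# TSD


def detect_tsd(
    genome: dict[str, str],
    locus,
    k_min: int = 4,
    k_max: int = 6,
) -> TsdCall:
    """Longest exact duplication of 4-6 bp immediately flanking the locus.

    Loci at a contig edge, or with N inside either flank, are reported as
    not determinable (the draft-assembly "N/A" case).
    """
    gseq = genome[locus.chrom].upper()
    s, e = locus.start, locus.end
    if s - k_max < 0 or e + k_max > len(gseq):
        return TsdCall(None, determinable=False, note="locus at contig edge")
    if "N" in gseq[s - k_max : s] or "N" in gseq[e : e + k_max]:
        return TsdCall(None, determinable=False, note="assembly gap in flank")
    for k in range(k_max, k_min - 1, -1):
        left, right = gseq[s - k : s], gseq[e : e + k]
        if left == right:
            return TsdCall(left, (s - k, s), (e, e + k))
    return TsdCall(None)


# ---------------------------------------------------------------------------
# PBS


def detect_pbs(
    locus_seq: str,
    ltr5_end: Optional[int],
    trna_library: Optional[dict[str, str]] = None,
    max_mismatch: int = 2,
    max_offset: int = 5,
    min_match: int = 16,
) -> Optional[PbsCall]:
    """Best reverse-complement match of a tRNA 3' end just after the 5' LTR.

    The PBS must begin within ``max_offset`` bp of the LTR end; candidates
    are ranked by mismatch count, then by match length.  Returns None when
    nothing matches within ``max_mismatch``.
    """
    if ltr5_end is None:
        raise ValueError("PBS requires 5' LTR")
    if trna_library is None:
        trna_library = load_trna_library()
    seq = locus_seq.upper()
    best: Optional[tuple[int, int, PbsCall]] = None
    for name in sorted(trna_library):
        tail = trna_library[name].upper()
        if len(tail) < min_match:
            continue
        probe = revcomp(tail)
        m = len(probe)
        for off in range(max_offset + 1):
            s = ltr5_end + off
            window = seq[s : s + m]
            if len(window) < m:
                continue
            mm = sum(a != b for a, b in zip(probe, window))
            if mm <= max_mismatch:
                key = (mm, -m)
                call = PbsCall(name, m, mm, (s, s + m))
                if best is None or key < best[:2]:
                    best = (mm, -m, call)
    return best[2] if best else None


# ---------------------------------------------------------------------------
# putein reconstruction

_NEG = -1e9

_CODON_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_AA:
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    _CODON_AA[a + b + c] = str(Seq(a + b + c).translate())
    return _CODON_AA


def _aa_score_row(matrix, aidx, ref_idx, aa: str, stop_penalty: float):
    """Score of one emitted amino acid against every reference residue."""
    arr = np.asarray(matrix)
    if aa == "*":
        return np.full(len(ref_idx), stop_penalty), aa
    if aa == "X":
        return np.zeros(len(ref_idx)), aa
    return arr[aidx[aa], ref_idx].astype(float), aa


def _repair_tables(matrix, ref: str, stop_penalty: float):
    """Best-translation score rows for frameshift codons.

    A 2-nt frameshift codon (1-nt deletion) may have lost a base at any of
    three positions; a 4-nt one (1-nt insertion) carries one surplus base.
    Each k-mer therefore maps to a small set of candidate amino acids; the
    move scores the best candidate against the reference residue.
    Returns (R2, R2_aa, R4, R4_aa, kmer index dicts).
    """
    table = _codon_table()
    alpha = matrix.alphabet
    aidx = {c: i for i, c in enumerate(alpha)}
    ref_idx = np.array([aidx.get(r, aidx["X"]) for r in ref.upper()], dtype=int)

    def best_rows(cands_per_kmer):
        kmers = sorted(cands_per_kmer)
        R = np.full((len(kmers), len(ref)), _NEG)
        best_aa = np.full((len(kmers), len(ref)), "X", dtype="U1")
        for t, kmer in enumerate(kmers):
            for aa in sorted(cands_per_kmer[kmer]):
                row, _ = _aa_score_row(matrix, aidx, ref_idx, aa, stop_penalty)
                better = row > R[t]
                R[t][better] = row[better]
                best_aa[t][better] = aa
        return {k: t for t, k in enumerate(kmers)}, R, best_aa

    two: dict[str, set] = {}
    for a in "ACGT":
        for b in "ACGT":
            cands = set()
            for pos in range(3):
                for x in "ACGT":
                    codon = (a + b)[:pos] + x + (a + b)[pos:]
                    cands.add(table[codon])
            two[a + b] = cands
    four: dict[str, set] = {}
    for kmer in ["".join(p) for p in __import__("itertools").product("ACGT", repeat=4)]:
        four[kmer] = {table[kmer[:d] + kmer[d + 1 :]] for d in range(4)}
    idx2, R2, A2 = best_rows(two)
    idx4, R4, A4 = best_rows(four)
    return aidx, ref_idx, idx2, R2, A2, idx4, R4, A4


def reconstruct_putein(
    locus_nt: str,
    reference_protein: str,
    gene: str = "unknown",
    frameshift_penalty: float = -20.0,
    stop_penalty: float = -10.0,
    ref_gap_penalty: float = -8.0,
) -> Putein:
    """Frameshift-aware translated alignment of DNA against a reference protein.

    Semi-global dynamic program (reference aligned in full, free nucleotide
    ends) over BLOSUM62 codon scores with five moves per cell: a codon match
    (3 nt); 2-nt and 4-nt frameshift codons (a 1-nt deletion or insertion
    inside the codon, charged ``frameshift_penalty`` and emitting the best
    repair-compatible translation); a bare 1-nt frameshift insertion between
    codons; and a reference gap.  In-frame stops translate as 'X' under
    ``stop_penalty``.  Percent identity is over emitted (aligned) columns.
    """
    nt = locus_nt.upper().replace("-", "")
    ref = reference_protein.upper()
    if not ref:
        raise ValueError("reference protein is empty")
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    blosum = substitution_matrices.load("BLOSUM62")
    table = _codon_table()
    aidx, ref_idx, idx2, R2, A2, idx4, R4, A4 = _repair_tables(
        blosum, ref, stop_penalty
    )
    arr = np.asarray(blosum)
    n, m = len(nt), len(ref)
    fs, gp = frameshift_penalty, ref_gap_penalty

    aa3 = np.array([table.get(nt[i : i + 3], "X") for i in range(max(n - 2, 0))],
                   dtype="U1")
    aa3_i = np.array([aidx.get(a, aidx["X"]) for a in aa3], dtype=int)
    is_stop = aa3 == "*"
    is_x = np.array([a not in aidx or a == "X" for a in aa3])
    t2 = np.array([idx2.get(nt[i : i + 2], -1) for i in range(max(n - 1, 0))],
                  dtype=int)
    t4 = np.array([idx4.get(nt[i : i + 4], -1) for i in range(max(n - 3, 0))],
                  dtype=int)

    def match_col(j):  # scores of codon starting at i, vs ref[j]
        col = arr[aa3_i, ref_idx[j]].astype(float)
        col[is_stop] = stop_penalty
        col[is_x] = 0.0
        return col

    def fs2_col(j):
        col = np.where(t2 >= 0, R2[np.maximum(t2, 0), j], 0.0)
        return col

    def fs4_col(j):
        if len(t4) == 0:
            return np.zeros(0)
        return np.where(t4 >= 0, R4[np.maximum(t4, 0), j], 0.0)

    S = np.full((m + 1, n + 1), _NEG)
    S[0, :] = 0.0  # free start in the nucleotide sequence
    for j in range(1, m + 1):
        row = np.full(n + 1, _NEG)
        prev = S[j - 1]
        row[3:] = np.maximum(row[3:], prev[:-3] + match_col(j - 1)[: n - 2])
        row[2:] = np.maximum(row[2:], prev[:-2] + fs + fs2_col(j - 1)[: n - 1])
        if n >= 4:
            row[4:] = np.maximum(row[4:], prev[:-4] + fs + fs4_col(j - 1)[: n - 3])
        row = np.maximum(row, prev + gp)
        # bare frameshift insertion within the row: S[j,i]=max(row[i], S[j,i-1]+fs)
        shift = fs * np.arange(n + 1)
        u = np.maximum.accumulate(row - shift)
        S[j] = u + shift

    end_i = int(np.argmax(S[m]))
    j, i = m, end_i
    emitted: list[str] = []
    ref_emitted: list[str] = []
    n_fs = 0
    eps = 1e-6
    while j > 0:
        v = S[j, i]
        if i >= 3 and abs(S[j - 1, i - 3] + match_col(j - 1)[i - 3] - v) < eps:
            emitted.append("X" if aa3[i - 3] == "*" else str(aa3[i - 3]))
            ref_emitted.append(ref[j - 1])
            j, i = j - 1, i - 3
        elif i >= 2 and t2[i - 2] >= 0 and abs(
            S[j - 1, i - 2] + fs + R2[t2[i - 2], j - 1] - v
        ) < eps:
            emitted.append(str(A2[t2[i - 2], j - 1]))
            ref_emitted.append(ref[j - 1])
            n_fs += 1
            j, i = j - 1, i - 2
        elif i >= 4 and t4[i - 4] >= 0 and abs(
            S[j - 1, i - 4] + fs + R4[t4[i - 4], j - 1] - v
        ) < eps:
            emitted.append(str(A4[t4[i - 4], j - 1]))
            ref_emitted.append(ref[j - 1])
            n_fs += 1
            j, i = j - 1, i - 4
        elif i >= 1 and abs(S[j, i - 1] + fs - v) < eps:
            n_fs += 1
            i -= 1
        elif abs(S[j - 1, i] + gp - v) < eps:
            j -= 1
        else:  # numerical fallback; should not happen
            raise RuntimeError("backtrack failed")
    start_i = i
    emitted.reverse()
    ref_emitted.reverse()
    n_cols = len(emitted)
    ident = (
        100.0 * sum(a == b for a, b in zip(emitted, ref_emitted)) / n_cols
        if n_cols
        else 0.0
    )
    return Putein(
        gene=gene,
        sequence="".join(emitted),
        frameshift_count=n_fs,
        percent_identity=ident,
        interval=(start_i, end_i),
        score=float(S[m, end_i]),
    )
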