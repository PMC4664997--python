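"""Majority-rule consensus building and LTR subgroup assignment.

LTR families commonly split into sequence subgroups defined by shared
diagnostic substitutions; a sequence that matches one subgroup's diagnostic
alleles over one span and the other subgroup's over another is a putative
recombinant.  Subgroups are found by average-linkage clustering on pairwise
K2P distances cut at two groups; diagnostic columns are those where the two
group consensuses differ with at least 80% within-group agreement.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import AlignIO, SeqIO
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dating import SaturationError, k2p_distance

__all__ = [
    "Msa",
    "SubgroupAssignment",
    "majority_consensus",
    "assign_subgroups",
    "mafft_align",
]

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class Msa:
    """A named multiple alignment over {A,C,G,T,N,-}."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names/seqs length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lens = {len(s) for s in self.seqs}
        if len(lens) > 1:
            raise ValueError("unequal alignment lengths")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __getitem__(self, name: str) -> str:
        return self.seqs[self.names.index(name)]

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        aln = AlignIO.read(str(path), "fasta")
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, s in zip(self.names, self.seqs):
                fh.write(f">{n}\n{s}\n")


@dataclass
class SubgroupAssignment:
    labels: dict[str, str]  # name -> A | B | recombinant | unassigned
    diagnostic_columns: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = set(self.diagnostic_columns.get("A", ()))
        b = set(self.diagnostic_columns.get("B", ()))
        if a & b:
            raise ValueError("diagnostic columns must be disjoint between groups")


def majority_consensus(msa: Msa, gap_rule: str = "drop", tie_rule: str = "iupac") -> str:
    """Per-column plurality base.  Columns where gap outnumbers every base are
    dropped (``gap_rule='drop'``) or emitted as '-' (``'keep'``); ties between
    bases become IUPAC ambiguity codes (``tie_rule='iupac'``) or the
    alphabetically first base (``'first'``)."""
    if msa.n_seqs < 1:
        raise ValueError("empty alignment")
    arr = msa.to_array()
    out = []
    for col in arr.T:
        counts = {b: int(np.sum(col == b)) for b in "ACGT"}
        gaps = int(np.sum(col == "-"))
        top = max(counts.values())
        if gaps > top:
            if gap_rule == "keep":
                out.append("-")
            continue
        if top == 0:
            out.append("N")
            continue
        winners = frozenset(b for b, c in counts.items() if c == top)
        if len(winners) == 1 or tie_rule == "first":
            out.append(sorted(winners)[0])
        else:
            out.append(_IUPAC[winners])
    return "".join(out)


def _pairwise_distance(a: str, b: str) -> float:
    try:
        d, *_ = k2p_distance(a, b, exclude_cpg=False)
        return d
    except SaturationError:
        pass
    except ValueError:
        return 1.0
    used = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    if not used:
        return 1.0
    return sum(x != y for x, y in used) / len(used)


def _group_consensus(arr: np.ndarray, rows: np.ndarray, col: int) -> Optional[str]:
    """Majority base of a column within a group; None if no base present."""
    col_vals = arr[rows, col]
    counts = [(int(np.sum(col_vals == b)), b) for b in "ACGT"]
    n, b = max(counts)
    if n == 0:
        return None
    return b


def assign_subgroups(msa: Msa, min_diag_sites: int = 3) -> SubgroupAssignment:
    """Two-group partition of aligned LTRs with recombinant flagging.

    Sequences whose diagnostic-site pattern matches one group over one span
    and the other group over a disjoint span (each span with at least
    ``min_diag_sites`` own-group matches and >=80% purity) are labelled
    recombinant and belong to neither group.  The larger group is called A.
    """
    if msa.n_seqs < 4:
        return SubgroupAssignment({n: "unassigned" for n in msa.names})
    arr = msa.to_array()
    n = msa.n_seqs

    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _pairwise_distance(msa.seqs[i], msa.seqs[j])
    clust = _two_group_partition(dm)
    clust = _refine_partition(arr, clust)

    labels = {name: None for name in msa.names}
    recomb: set[int] = set()
    diag_a: list[int] = []
    diag_b: list[int] = []
    breakpoints: dict[str, tuple[int, int]] = {}

    for _pass in range(2):
        rows1 = np.array(
            [i for i in range(n) if clust[i] == 1 and i not in recomb], dtype=int
        )
        rows2 = np.array(
            [i for i in range(n) if clust[i] == 2 and i not in recomb], dtype=int
        )
        if len(rows1) == 0 or len(rows2) == 0:
            return SubgroupAssignment({name: "A" for name in msa.names})
        # larger cluster is group A; ties broken by smallest member name
        key1 = (-len(rows1), min(msa.names[i] for i in rows1))
        key2 = (-len(rows2), min(msa.names[i] for i in rows2))
        ga, gb = (rows1, rows2) if key1 <= key2 else (rows2, rows1)

        cons_a: dict[int, str] = {}
        cons_b: dict[int, str] = {}
        diag: list[int] = []
        for c in range(msa.n_cols):
            col = arr[:, c]
            if np.sum(np.isin(col, list("ACGT"))) < 0.5 * n:
                continue  # poorly covered column (partial LTRs)
            a_base = _group_consensus(arr, ga, c)
            b_base = _group_consensus(arr, gb, c)
            if a_base is None or b_base is None or a_base == b_base:
                continue
            a_vals = arr[ga, c]
            b_vals = arr[gb, c]
            a_cov = np.isin(a_vals, list("ACGT"))
            b_cov = np.isin(b_vals, list("ACGT"))
            if not a_cov.any() or not b_cov.any():
                continue
            if (
                np.sum(a_vals == a_base) / max(1, a_cov.sum()) >= 0.8
                and np.sum(b_vals == b_base) / max(1, b_cov.sum()) >= 0.8
            ):
                diag.append(c)
                cons_a[c] = a_base
                cons_b[c] = b_base

        diag_a = diag_b = diag
        recomb = set()
        for i in range(n):
            state = []  # +1 matches A allele, -1 matches B allele, per diag col
            for c in diag:
                x = arr[i, c]
                if x == cons_a[c]:
                    state.append(1)
                elif x == cons_b[c]:
                    state.append(-1)
                else:
                    state.append(0)
            res = _call_sequence(state, min_diag_sites)
            if res[0] == "recombinant":
                recomb.add(i)
                if res[1] is not None:
                    cut = res[1]
                    breakpoints[msa.names[i]] = (
                        diag[cut - 1] + 1 if cut > 0 else 0,
                        diag[cut] + 1 if cut < len(diag) else msa.n_cols,
                    )
            labels[msa.names[i]] = res[0]
        if not recomb:
            break

    if not diag_a:
        return SubgroupAssignment({name: "A" for name in msa.names})
    # a column is "X-diagnostic" when group X carries the derived (non-overall-
    # consensus) allele; this keeps the per-group lists disjoint
    overall = {}
    for c in diag_a:
        col = arr[:, c]
        counts = [(int(np.sum(col == b)), b) for b in "ACGT"]
        overall[c] = max(counts)[1]
    per_group = {"A": [], "B": []}
    for c in diag_a:
        a_base = _group_consensus(arr, np.array([i for i in range(n) if labels[msa.names[i]] == "A"] or [0]), c)
        per_group["A" if a_base != overall[c] else "B"].append(c)
    asn = SubgroupAssignment(labels, per_group)
    asn.breakpoints = breakpoints  # alignment-column spans per recombinant
    return asn


def _two_group_partition(dm: np.ndarray) -> np.ndarray:
    """Initial 2-group split of a distance matrix.

    An average-linkage 2-cut isolates single noisy outliers, so the split is
    taken on the sign of the first principal coordinate (classical MDS of
    the distance matrix), where the group signal dominates individual noise;
    a degenerate axis falls back to the linkage cut."""
    n = dm.shape[0]
    d2 = dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    axis = v[:, -1]
    if np.all(axis >= 0) or np.all(axis <= 0) or w[-1] <= 1e-12:
        Z = linkage(squareform(dm, checks=False), method="average")
        return fcluster(Z, t=2, criterion="maxclust")
    # deterministic orientation: sequence 0 belongs to cluster 1
    if axis[0] < 0:
        axis = -axis
    return np.where(axis >= 0, 1, 2).astype(np.int32)


def _refine_partition(arr: np.ndarray, clust: np.ndarray) -> np.ndarray:
    """k-medoids-style polish of the 2-cut: reassign each sequence to the
    nearer group consensus until stable (guards against a hierarchical cut
    that isolates a single noisy sequence)."""
    n = arr.shape[0]
    clust = clust.copy()
    bases = np.array(list("ACGT"))

    def cons_of(rows):
        if len(rows) == 0:
            return None
        sub = arr[rows]
        counts = np.stack([(sub == b).sum(axis=0) for b in bases])
        return bases[np.argmax(counts, axis=0)]

    def dist_to(i, cons):
        ok = np.isin(arr[i], bases)
        if cons is None or not ok.any():
            return np.inf
        return float(np.mean(arr[i][ok] != cons[ok]))

    for _ in range(10):
        c1 = cons_of(np.flatnonzero(clust == 1))
        c2 = cons_of(np.flatnonzero(clust == 2))
        new = np.array(
            [1 if dist_to(i, c1) <= dist_to(i, c2) else 2 for i in range(n)],
            dtype=clust.dtype,
        )
        if len(set(new.tolist())) == 1:  # collapsed: keep previous partition
            break
        if np.array_equal(new, clust):
            break
        clust = new
    return clust


def _call_sequence(state: list[int], min_diag_sites: int):
    """Label one sequence from its diagnostic-site pattern.

    Returns (label, cut_index_into_diag_list_or_None)."""
    a = sum(1 for s in state if s == 1)
    b = sum(1 for s in state if s == -1)
    if a + b == 0:
        return ("unassigned", None)
    # best single changepoint: prefix one group, suffix the other
    best = None
    m = len(state)
    pre_a = np.cumsum([s == 1 for s in state])
    pre_b = np.cumsum([s == -1 for s in state])
    for cut in range(1, m):
        la, lb = int(pre_a[cut - 1]), int(pre_b[cut - 1])
        ra, rb = a - la, b - lb
        for left_lbl, lown, lother, rown, rother in (
            ("A", la, lb, rb, ra),  # A then B
            ("B", lb, la, ra, rb),  # B then A
        ):
            if lown >= min_diag_sites and rown >= min_diag_sites:
                if lown / max(1, lown + lother) >= 0.8 and rown / max(
                    1, rown + rother
                ) >= 0.8:
                    score = lown + rown
                    if best is None or score > best[0]:
                        best = (score, cut, left_lbl)
    plain = max(a, b)
    if best is not None and best[0] > plain:
        return ("recombinant", best[1])
    if a == b:
        return ("unassigned", None)
    return ("A" if a > b else "B", None)


def mafft_align(seqs: dict[str, str], mafft_path: str = "mafft") -> Msa:
    """Multiple alignment via the external mafft program (auto mode)."""
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for name, s in seqs.items():
                fh.write(f">{name}\n{s}\n")
        proc = subprocess.run(
            [mafft_path, "--auto", "--quiet", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
        aln = list(SeqIO.parse(StringIO(proc.stdout), "fasta"))
    return Msa([r.id for r in aln], [str(r.seq).upper() for r in aln])
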