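"""Insertion dating from 5'/3' LTR divergence under a host molecular clock.

At integration the two LTRs of a provirus are identical; afterwards each copy
accumulates substitutions at the neutral rate of the host genome.  The
Kimura 2-parameter (K2P) corrected divergence D between the 5' and 3' LTR
therefore dates the insertion as

    T = D / (2 r)

with r the host substitution rate in substitutions/site/Myr (default 0.0015,
a published rate for bears).  CpG dinucleotides are hypermutable in mammals
and are excluded from the distance by default: an alignment column is dropped
when EITHER sequence participates in a CpG at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
import numpy as np

from ._seq import PURINES

__all__ = [
    "SaturationError",
    "RecombinantLtrError",
    "DivergenceEstimate",
    "k2p_distance",
    "date_provirus",
    "align_pair",
]


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment of an LTR pair (needleman-wunsch, mild gap
    costs); returns the two gapped strings for distance computation."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -1
    aln = al.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    return s1, s2

_BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P logarithms undefined: divergence beyond the correctable range."""


class RecombinantLtrError(ValueError):
    """LTR pair flagged as recombinant: LTR-divergence dating is invalid (ND)."""


@dataclass
class DivergenceEstimate:
    """K2P divergence of an LTR pair and the implied insertion age."""

    P: float  # transition proportion over used sites
    Q: float  # transversion proportion over used sites
    D: float  # K2P distance
    n_sites_used: int
    n_cpg_excluded: int
    age_myr: float
    rate_used: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.age_myr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _classify_columns(seq1: str, seq2: str, exclude_cpg: bool):
    """Per usable column: 0 identical, 1 transition, 2 transversion.

    Usable columns are those where both sequences carry an unambiguous base
    and (if exclude_cpg) neither sequence is part of a CpG dinucleotide.
    Returns (categories array, n_excluded_cpg).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    n = len(s1)
    drop = set()
    if exclude_cpg:
        for s in (s1, s2):
            for i in range(n - 1):
                if s[i] == "C" and s[i + 1] == "G":
                    drop.add(i)
                    drop.add(i + 1)
    cats = []
    n_cpg = 0
    for i in range(n):
        a, b = s1[i], s2[i]
        if a not in _BASES or b not in _BASES:
            continue
        if i in drop:
            n_cpg += 1
            continue
        if a == b:
            cats.append(0)
        elif (a in PURINES) == (b in PURINES):
            cats.append(1)
        else:
            cats.append(2)
    return np.asarray(cats, dtype=np.int8), n_cpg


def _k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturation: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    return max(0.0, -0.5 * log(w1) - 0.25 * log(w2))


def k2p_distance(seq1: str, seq2: str, exclude_cpg: bool = True):
    """Kimura 2-parameter distance between two aligned sequences.

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) over non-gap, non-N columns,
    with CpG columns removed first when ``exclude_cpg``.

    Returns ``(D, P, Q, n_used, n_excluded)``.  Raises :class:`SaturationError`
    when a logarithm argument is non-positive.
    """
    cats, n_cpg = _classify_columns(seq1, seq2, exclude_cpg)
    n = len(cats)
    if n == 0:
        raise ValueError("no usable columns")
    P = float(np.count_nonzero(cats == 1)) / n
    Q = float(np.count_nonzero(cats == 2)) / n
    return _k2p_from_pq(P, Q), P, Q, n, n_cpg


def date_provirus(
    ltr5: str,
    ltr3: str,
    rate: float = 0.0015,
    exclude_cpg: bool = True,
    n_bootstrap: int = 1000,
    seed: int = 0,
    recombinant: bool = False,
    ci_level: float = 0.95,
) -> DivergenceEstimate:
    """Date a provirus from its aligned 5'/3' LTR pair: T = D/(2·rate).

    The confidence interval is a percentile bootstrap over alignment columns
    (category resampling, ``n_bootstrap`` replicates).  A pair with zero
    observed differences has a degenerate bootstrap, so its upper bound is
    the exact binomial (Clopper-Pearson) upper limit for 0 successes and the
    estimate is flagged ``young -- clock uninformative``.

    Pairs flagged recombinant are refused (:class:`RecombinantLtrError`):
    a mosaic LTR breaks the identical-at-integration premise (reported ND).
    """
    if recombinant:
        raise RecombinantLtrError("recombinant LTR pair: age not determinable (ND)")
    if rate <= 0:
        raise ValueError("rate must be positive")
    cats, n_cpg = _classify_columns(ltr5, ltr3, exclude_cpg)
    n = len(cats)
    if n == 0:
        raise ValueError("no usable columns")
    counts = np.bincount(cats, minlength=3).astype(float)
    P, Q = counts[1] / n, counts[2] / n
    D = _k2p_from_pq(P, Q)
    T = D / (2.0 * rate)
    flags: list[str] = []
    alpha = 1.0 - ci_level

    n_diff = int(counts[1] + counts[2])
    if n_diff == 0:
        # Degenerate bootstrap; exact binomial upper bound for 0/n.
        p_hi = 1.0 - (alpha / 2.0) ** (1.0 / n)
        ci_low, ci_high = 0.0, p_hi / (2.0 * rate)
        flags.append("young -- clock uninformative")
    else:
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, counts / n, size=n_bootstrap).astype(float)
        Pb, Qb = draws[:, 1] / n, draws[:, 2] / n
        w1 = 1.0 - 2.0 * Pb - Qb
        w2 = 1.0 - 2.0 * Qb
        ok = (w1 > 0) & (w2 > 0)
        Db = -0.5 * np.log(w1[ok]) - 0.25 * np.log(w2[ok])
        Tb = Db / (2.0 * rate)
        ci_low, ci_high = (
            float(np.percentile(Tb, 100 * alpha / 2)),
            float(np.percentile(Tb, 100 * (1 - alpha / 2))),
        )
        ci_low = max(0.0, min(ci_low, T))
        ci_high = max(ci_high, T)

    return DivergenceEstimate(
        P=P,
        Q=Q,
        D=D,
        n_sites_used=n,
        n_cpg_excluded=n_cpg,
        age_myr=T,
        rate_used=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        flags=tuple(flags),
    )
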