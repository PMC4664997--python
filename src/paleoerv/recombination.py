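"""Recombination detection in LTR alignments.

Two complementary scans:

* ``savings_scan`` -- explain a target sequence column-by-column as a copy of
  one of the other alignment rows, charging 1 per mismatch and ``alpha`` per
  change of source.  The "savings" is the mutational cost avoided relative to
  the best single source; its significance is assessed by permuting column
  order (add-one permutation p-value, so the floor at 1000 permutations is
  1/1001 ~= 0.000999).
* ``sliding_window_scan`` -- nearest reference by p-distance per window; a
  change of nearest reference between consecutive windows marks a candidate
  breakpoint region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .consensus import Msa

__all__ = [
    "RecombinationResult",
    "WindowCall",
    "savings_scan",
    "sliding_window_scan",
]


@dataclass(frozen=True)
class RecombinationResult:
    sequence: str
    start: int  # 1-based inclusive alignment columns bracketing the breakpoint
    end: int
    savings: float
    p_value: float
    source_left: Optional[str] = None
    source_right: Optional[str] = None
    n_switches: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.savings < 0:
            raise ValueError("savings must be >= 0")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value out of (0,1]")


def _cost_matrix(msa: Msa, target: str) -> tuple[np.ndarray, list[str]]:
    """cost[s, c] = 1 if target mismatches source s at column c (N free)."""
    if target not in msa.names:
        raise KeyError(target)
    arr = msa.to_array()
    ti = msa.names.index(target)
    sources = [n for n in msa.names if n != target]
    rows = [msa.names.index(n) for n in sources]
    t = arr[ti]
    C = (arr[rows] != t[None, :]).astype(np.int64)
    free = (arr[rows] == "N") | (t[None, :] == "N")
    C[free] = 0
    return C, sources


def _dp(C: np.ndarray, alpha: float):
    """Min-cost source path; returns (cost, path of source indices)."""
    S, m = C.shape
    V = C[:, 0].astype(float)
    back = np.zeros((m, S), dtype=np.int64)
    back[0] = np.arange(S)
    for c in range(1, m):
        j = int(np.argmin(V))  # lowest index wins ties (stable argmin)
        switch = V[j] + alpha
        stay = V
        take_switch = switch < stay  # strict: prefer staying on ties
        back[c] = np.where(take_switch, j, np.arange(S))
        V = np.where(take_switch, switch, stay) + C[:, c]
    end = int(np.argmin(V))
    cost = float(V[end])
    path = np.empty(m, dtype=np.int64)
    path[m - 1] = end
    for c in range(m - 1, 0, -1):
        path[c - 1] = back[c][path[c]]
    return cost, path


def _batched_min_cost(C_perms: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised minimal path cost for a batch of column-permuted matrices."""
    B, S, m = C_perms.shape
    V = C_perms[:, :, 0].astype(float)
    for c in range(1, m):
        best = V.min(axis=1, keepdims=True)
        V = np.minimum(V, best + alpha) + C_perms[:, :, c]
    return V.min(axis=1)


def savings_scan(
    msa: Msa,
    target: str,
    alpha: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RecombinationResult:
    """Mutational-cost savings of a mosaic explanation of ``target``.

    ``savings = cost0 - costR`` where cost0 is the best single-source cost
    and costR the best multi-source path cost (switches charged ``alpha``).
    The breakpoint interval runs from one past the last column supporting
    the left-hand source to the first column supporting the right-hand one
    ("supporting": the target matches that source and not the other).  When
    several switches occur, the one with the greatest local savings is
    reported.  The p-value permutes alignment column order.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    C, sources = _cost_matrix(msa, target)
    if len(sources) < 2:
        raise ValueError("need at least two non-target sequences")
    m = C.shape[1]
    cost0 = float(C.sum(axis=1).min())
    costR, path = _dp(C, alpha)
    savings = cost0 - costR

    start = end = 1
    src_l = src_r = None
    n_switch = int(np.sum(path[1:] != path[:-1]))
    if n_switch > 0 and savings > 0:
        best_gain = None
        switch_cols = np.flatnonzero(path[1:] != path[:-1]) + 1  # col after switch
        for sc in switch_cols:
            sl, sr = int(path[sc - 1]), int(path[sc])
            lo = switch_cols[switch_cols < sc]
            hi = switch_cols[switch_cols > sc]
            seg_lo = int(lo[-1]) if len(lo) else 0
            seg_hi = int(hi[0]) if len(hi) else m
            seg = slice(seg_lo, seg_hi)
            mosaic = C[sl, seg_lo:sc].sum() + C[sr, sc:seg_hi].sum() + alpha
            single = min(C[sl, seg].sum(), C[sr, seg].sum())
            gain = single - mosaic
            if best_gain is None or gain > best_gain[0]:
                best_gain = (gain, sc, sl, sr)
        _, sc, sl, sr = best_gain
        support_l = np.flatnonzero((C[sl, :sc] == 0) & (C[sr, :sc] == 1))
        support_r = np.flatnonzero((C[sr, sc:] == 0) & (C[sl, sc:] == 1)) + sc
        last_l = int(support_l[-1]) if len(support_l) else sc - 1
        first_r = int(support_r[0]) if len(support_r) else sc
        start, end = last_l + 2, first_r + 1  # 1-based
        if start > end:
            start = end
        src_l, src_r = sources[sl], sources[sr]

    rng = np.random.default_rng(seed)
    if n_permutations > 0:
        perms = np.argsort(rng.random((n_permutations, m)), axis=1)
        Cp = C[:, perms]  # (S, B, m)
        Cp = np.transpose(Cp, (1, 0, 2))
        costR_perm = _batched_min_cost(Cp, alpha)
        sav_perm = cost0 - costR_perm
        p = (1.0 + float(np.sum(sav_perm >= savings))) / (n_permutations + 1.0)
    else:
        p = 1.0

    return RecombinationResult(
        sequence=target,
        start=start,
        end=end,
        savings=savings,
        p_value=p,
        source_left=src_l,
        source_right=src_r,
        n_switches=n_switch,
    )


@dataclass(frozen=True)
class WindowCall:
    start: int  # 1-based inclusive alignment columns
    end: int
    nearest: str
    distance: float


def sliding_window_scan(
    msa: Msa,
    target: str,
    window: int = 100,
    step: int = 20,
) -> list[WindowCall]:
    """Nearest reference (p-distance) per sliding window.

    Ties keep the previous window's reference when possible so that only
    genuine changes of nearest reference mark candidate breakpoints.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window > msa.n_cols:
        raise ValueError("window exceeds alignment length")
    arr = msa.to_array()
    ti = msa.names.index(target)
    sources = [n for n in msa.names if n != target]
    rows = [msa.names.index(n) for n in sources]
    t = arr[ti]
    diff = (arr[rows] != t[None, :]).astype(float)
    usable = ~((arr[rows] == "N") | (t[None, :] == "N"))
    diff = diff * usable

    calls: list[WindowCall] = []
    prev: Optional[str] = None
    starts = list(range(0, msa.n_cols - window + 1, step))
    if starts and starts[-1] + window < msa.n_cols:
        starts.append(msa.n_cols - window)
    for s in starts:
        seg = slice(s, s + window)
        nvalid = usable[:, seg].sum(axis=1)
        d = np.where(nvalid > 0, diff[:, seg].sum(axis=1) / np.maximum(nvalid, 1), np.inf)
        dmin = d.min()
        cands = [sources[i] for i in np.flatnonzero(d == dmin)]
        nearest = prev if prev in cands else cands[0]
        calls.append(WindowCall(s + 1, s + window, nearest, float(dmin)))
        prev = nearest
    return calls
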