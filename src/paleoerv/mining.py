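"""Candidate ERV locus discovery and LTR boundary refinement.

Mining is a seed-and-extend local search: exact k-mer seeds between the
genome and a retroviral query (both strands) are extended ungapped with an
x-drop rule, and nearby hits on the same strand are merged so that a
gap-interrupted provirus still reports as one candidate.

Refinement then looks inside a flanked window for the structure that defines
an ERV insertion: a near-identical direct repeat pair (the two LTRs) for a
provirus, or a single LTR-sized match for a solo LTR.  Outer boundaries are
snapped to the candidate offset that best shows the signatures integration
leaves behind -- an exact flanking target-site duplication and the canonical
5'-TG...CA-3' LTR termini.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from Bio import Align

from ._seq import n_runs, revcomp

__all__ = [
    "CandidateHit",
    "ErvLocus",
    "LocusCounts",
    "find_candidate_loci",
    "refine_boundaries",
    "classify_loci",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class CandidateHit:
    chrom: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    percent_identity: float
    query_id: str
    score: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty interval")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("identity out of range")


@dataclass
class ErvLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # provirus | solo_ltr | partial
    ltr5_interval: Optional[tuple[int, int]] = None
    ltr3_interval: Optional[tuple[int, int]] = None
    gap_intervals: tuple[tuple[int, int], ...] = ()
    tsd_seq: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        for iv in (self.ltr5_interval, self.ltr3_interval):
            if iv is not None and not (self.start <= iv[0] < iv[1] <= self.end):
                raise ValueError("LTR interval outside locus")
        if self.kind == "provirus" and (
            self.ltr5_interval is None or self.ltr3_interval is None
        ):
            raise ValueError("provirus requires both LTRs")
        if self.kind == "solo_ltr":
            if self.ltr5_interval != (self.start, self.end):
                raise ValueError("solo LTR must equal its locus")


# ---------------------------------------------------------------------------
# seed and extend


def _check_alphabet(name: str, seq: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"{name}: non-ACGTN characters {sorted(bad)!r}")


def _extend(gseq: str, qseq: str, gpos: int, qpos: int, k: int, match: int,
            mismatch: int, xdrop: int):
    """Ungapped x-drop extension of an exact k-mer seed.

    Returns (gstart, gend, qstart, qend, score, matches)."""
    score = best = k * match
    matches = best_matches = k
    # right
    gi, qi = gpos + k, qpos + k
    bg, bq = gi, qi
    while gi < len(gseq) and qi < len(qseq):
        score += match if gseq[gi] == qseq[qi] else mismatch
        if gseq[gi] == qseq[qi]:
            matches += 1
        gi += 1
        qi += 1
        if score > best:
            best, bg, bq, best_matches = score, gi, qi, matches
        elif best - score > xdrop:
            break
    gend, qend = bg, bq
    score, matches = best, best_matches
    # left
    gi, qi = gpos - 1, qpos - 1
    bg, bq = gpos, qpos
    cur = score
    best = score
    best_matches = matches
    while gi >= 0 and qi >= 0:
        cur += match if gseq[gi] == qseq[qi] else mismatch
        if gseq[gi] == qseq[qi]:
            matches += 1
        if cur > best:
            best, bg, bq, best_matches = cur, gi, qi, matches
        elif best - cur > xdrop:
            break
        gi -= 1
        qi -= 1
    return bg, gend, bq, qend, best, best_matches


def find_candidate_loci(
    genome: dict[str, str],
    queries: dict[str, str],
    min_identity: float = 80.0,
    min_length: int = 200,
    seed_k: int = 12,
    xdrop: int = 20,
    match: int = 1,
    mismatch: int = -2,
    merge_gap: int = 2000,
) -> list[CandidateHit]:
    """Seed-and-extend search of ``queries`` against ``genome``, both strands.

    Hits below ``min_identity`` percent or ``min_length`` bp are discarded;
    same-strand hits separated by at most ``merge_gap`` bp are merged.
    """
    if seed_k < 8:
        raise ValueError("seed_k must be >= 8")
    if not queries:
        raise ValueError("queries must be non-empty")
    for name, q in queries.items():
        _check_alphabet(f"query {name}", q)
    raw: list[CandidateHit] = []
    for chrom in sorted(genome):
        gseq = genome[chrom].upper()
        _check_alphabet(chrom, gseq)
        for qid in sorted(queries):
            for strand in "+-":
                qseq = queries[qid].upper()
                if strand == "-":
                    qseq = revcomp(qseq)
                index: dict[str, list[int]] = {}
                for i in range(len(qseq) - seed_k + 1):
                    kmer = qseq[i : i + seed_k]
                    if "N" not in kmer:
                        index.setdefault(kmer, []).append(i)
                covered: dict[int, int] = {}  # diagonal -> genome end covered
                for g in range(len(gseq) - seed_k + 1):
                    kmer = gseq[g : g + seed_k]
                    for q in index.get(kmer, ()):  # noqa: B007
                        diag = g - q
                        if covered.get(diag, -1) >= g + seed_k:
                            continue
                        gs, ge, qs, qe, score, matches = _extend(
                            gseq, qseq, g, q, seed_k, match, mismatch, xdrop
                        )
                        covered[diag] = ge
                        length = ge - gs
                        ident = 100.0 * matches / length
                        if length >= min_length and ident >= min_identity:
                            raw.append(
                                CandidateHit(
                                    chrom=chrom,
                                    start=gs,
                                    end=ge,
                                    strand=strand,
                                    percent_identity=ident,
                                    query_id=qid,
                                    score=score,
                                )
                            )
    return _merge_hits(raw, merge_gap)


def _merge_hits(hits: list[CandidateHit], merge_gap: int) -> list[CandidateHit]:
    out: list[CandidateHit] = []
    key = lambda h: (h.chrom, h.strand, h.query_id, h.start)
    for h in sorted(hits, key=key):
        if out:
            p = out[-1]
            if (
                p.chrom == h.chrom
                and p.strand == h.strand
                and p.query_id == h.query_id
                and h.start - p.end <= merge_gap
            ):
                la, lb = p.end - p.start, max(h.end, p.end) - min(h.start, p.start)
                lh = h.end - h.start
                ident = (p.percent_identity * la + h.percent_identity * lh) / (la + lh)
                out[-1] = replace(
                    p,
                    start=min(p.start, h.start),
                    end=max(p.end, h.end),
                    score=p.score + h.score,
                    percent_identity=min(100.0, ident),
                )
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# boundary refinement


def _aligner(local=True) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    # harsh mismatch cost keeps terminal random-sequence extensions out
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -7
    a.extend_gap_score = -2
    return a


def _alignment_identity(aln) -> float:
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total if total else 0.0


def _snap_edges(gseq: str, start: int, end: int, slack: int = 10,
                k_min: int = 4, k_max: int = 5):
    """Choose outer edges near (start, end) maximising integration signatures:
    an exact flanking TSD (weight ~2 per bp) plus TG.../...CA termini."""
    best = (-1, 0, 0)  # score, |shift|, ...
    chosen = (start, end, None)
    for ds in range(-slack, slack + 1):
        s = start + ds
        if s < 0 or s + 2 > len(gseq):
            continue
        for de in range(-slack, slack + 1):
            e = end + de
            if e > len(gseq) or e - 2 < 0 or e <= s:
                continue
            score = 0
            if gseq[s : s + 2] == "TG":
                score += 2
            if gseq[e - 2 : e] == "CA":
                score += 2
            tsd = None
            for k in range(k_max, k_min - 1, -1):
                if s - k < 0 or e + k > len(gseq):
                    continue
                left, right = gseq[s - k : s], gseq[e : e + k]
                if left == right and "N" not in left:
                    tsd = left
                    score += 2 * k
                    break
            cand = (score, -(abs(ds) + abs(de)))
            if cand > (best[0], best[1]):
                best = (cand[0], cand[1], 0)
                chosen = (s, e, tsd)
    return chosen


def refine_boundaries(
    genome: dict[str, str],
    hit: CandidateHit,
    flank: int = 1000,
    ltr_min: int = 300,
    ltr_max: int = 1200,
    min_ltr_identity: float = 85.0,
    query_ltr: Optional[str] = None,
    locus_id: Optional[str] = None,
) -> ErvLocus:
    """Delineate the LTR structure of a candidate hit.

    The hit is expanded by ``flank`` bp and searched for a direct repeat
    pair of LTR-like length/identity by local self-alignment of the window's
    two ends.  If no pair is found and ``query_ltr`` is given, a single LTR
    is sought by local alignment against it (solo LTR); otherwise the locus
    is reported as ``partial``.  Outer edges are snapped to TSD / TG...CA
    signatures.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    gseq = genome[hit.chrom].upper()
    w0 = max(0, hit.start - flank)
    w1 = min(len(gseq), hit.end + flank)
    window = gseq[w0:w1]
    lid = locus_id or f"{hit.chrom}:{hit.start}-{hit.end}"
    aligner = _aligner()

    # --- direct repeat (LTR pair) search across the window's two ends
    ltr5 = ltr3 = None
    if len(window) >= 2 * ltr_min:
        half = min(len(window) // 2, ltr_max + flank + 500)
        L, R = window[:half], window[-half:]
        r_off = len(window) - half
        try:
            aln = aligner.align(L, R)[0]
        except (IndexError, ValueError):
            aln = None
        if aln is not None:
            ls, le = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            rs, re = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
            length5, length3 = le - ls, re - rs
            ident = _alignment_identity(aln)
            if (
                ltr_min <= length5 <= ltr_max
                and ltr_min <= length3 <= ltr_max
                and ident >= min_ltr_identity
            ):
                ltr5 = (w0 + ls, w0 + le)
                ltr3 = (w0 + r_off + rs, w0 + r_off + re)

    if ltr5 and ltr3 and ltr3[0] > ltr5[1]:
        len5, len3 = ltr5[1] - ltr5[0], ltr3[1] - ltr3[0]
        s, e, tsd = _snap_edges(gseq, ltr5[0], ltr3[1])
        locus = ErvLocus(
            locus_id=lid,
            chrom=hit.chrom,
            start=s,
            end=e,
            strand=hit.strand,
            kind="provirus",
            ltr5_interval=(s, min(s + len5, e)),
            ltr3_interval=(max(e - len3, s), e),
            tsd_seq=tsd,
        )
        locus.gap_intervals = tuple(
            (a + locus.start, b + locus.start)
            for a, b in n_runs(gseq[locus.start : locus.end])
        )
        return locus

    # --- single LTR (solo) search
    if query_ltr:
        try:
            aln = aligner.align(window, query_ltr.upper())[0]
        except (IndexError, ValueError):
            aln = None
        if aln is not None:
            ws, we = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            ident = _alignment_identity(aln)
            if ltr_min <= we - ws <= ltr_max and ident >= min_ltr_identity:
                s, e, tsd = _snap_edges(gseq, w0 + ws, w0 + we)
                locus = ErvLocus(
                    locus_id=lid,
                    chrom=hit.chrom,
                    start=s,
                    end=e,
                    strand=hit.strand,
                    kind="solo_ltr",
                    ltr5_interval=(s, e),
                    tsd_seq=tsd,
                )
                locus.gap_intervals = tuple(
                    (a + s, b + s) for a, b in n_runs(gseq[s:e])
                )
                return locus

    return ErvLocus(
        locus_id=lid,
        chrom=hit.chrom,
        start=hit.start,
        end=hit.end,
        strand=hit.strand,
        kind="partial",
        gap_intervals=tuple(
            (a + hit.start, b + hit.start) for a, b in n_runs(gseq[hit.start : hit.end])
        ),
        notes="no LTR pair and no single LTR-like match in window",
    )


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class LocusCounts:
    proviruses: int
    solo_ltrs: int
    partial: int
    total_ltrs: int


def classify_loci(loci: list[ErvLocus]) -> LocusCounts:
    """Summary counts; total LTRs = 2 per full provirus + 1 per solo LTR +
    1 per partial locus that still shows a single LTR."""
    prov = sum(1 for l in loci if l.kind == "provirus")
    solo = sum(1 for l in loci if l.kind == "solo_ltr")
    part = sum(1 for l in loci if l.kind == "partial")
    partial_ltrs = sum(
        1
        for l in loci
        if l.kind == "partial"
        and (l.ltr5_interval is not None) ^ (l.ltr3_interval is not None)
    )
    return LocusCounts(prov, solo, part, 2 * prov + solo + partial_ltrs)
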