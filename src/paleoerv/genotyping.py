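"""Insertion presence/absence genotyping from junction-spanning sequence.

For every characterised locus three diagnostic haplotype probes are built:
the two integrated-allele junctions (host flank -> LTR end, on both sides)
and the pre-integration empty site (the two flanks joined across a single
copy of the TSD, since integration duplicated it).  A read supports an
allele when it covers the junction point of a probe with at least
``min_overhang`` bases on each side and at most ``max_mismatch`` mismatches.
An in-silico PCR utility mirrors the wet-lab confirmation assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO

from ._seq import revcomp

__all__ = [
    "JunctionAssay",
    "JunctionGenotype",
    "build_assays",
    "genotype_sample",
    "in_silico_pcr",
]


@dataclass
class JunctionAssay:
    locus_id: str
    left_flank: str
    right_flank: str
    tsd: str
    integrated_left: Optional[str]  # flank + 5' LTR head
    integrated_right: Optional[str]  # 3' LTR tail + flank
    empty: Optional[str]  # left flank + one TSD copy + right flank
    junction_offsets: dict = field(default_factory=dict)  # probe -> junction pos
    reliable: bool = True
    note: str = ""


@dataclass
class JunctionGenotype:
    locus_id: str
    sample_id: str
    state: str  # present | absent | both | no_data
    reads_supporting_integrated: int
    reads_supporting_empty: int


def build_assays(genome: dict[str, str], loci, flank_len: int = 60) -> list[JunctionAssay]:
    """Junction probes for each locus; the empty-site probe reconstructs the
    pre-integration haplotype by removing the element and ONE TSD copy.

    Loci at a contig edge get a one-sided assay; flanks with more than 20% N
    mark the assay unreliable.
    """
    assays = []
    for locus in loci:
        gseq = genome[locus.chrom].upper()
        s, e = locus.start, locus.end
        k = len(locus.tsd_seq) if getattr(locus, "tsd_seq", None) else 0
        left = gseq[max(0, s - flank_len) : s]
        right_src = gseq[e + k : e + k + flank_len]
        right_with_tsd = gseq[e : e + flank_len]
        inner_l = gseq[s : s + flank_len]
        inner_r = gseq[max(s, e - flank_len) : e]

        frac_n = lambda x: x.count("N") / len(x) if x else 1.0
        reliable = True
        note = ""
        if frac_n(left) > 0.2 or frac_n(right_with_tsd) > 0.2:
            reliable = False
            note = "flank >20% N"

        # `left` ends with the left TSD copy, so joining it directly to the
        # post-TSD right flank leaves exactly ONE TSD at the empty junction
        integ_l = left + inner_l if len(left) >= flank_len // 2 else None
        integ_r = inner_r + right_with_tsd if len(right_with_tsd) >= flank_len // 2 else None
        empty = (
            left + right_src
            if integ_l is not None and len(right_src) >= flank_len // 2
            else None
        )
        if integ_l is None or integ_r is None:
            note = (note + "; " if note else "") + "one-sided (contig edge)"
        offsets = {}
        if integ_l is not None:
            offsets["integrated_left"] = len(left)
        if integ_r is not None:
            offsets["integrated_right"] = len(inner_r)
        if empty is not None:
            offsets["empty"] = len(left)  # junction right after the single TSD
        assays.append(
            JunctionAssay(
                locus_id=locus.locus_id if hasattr(locus, "locus_id") else locus.feature_id,
                left_flank=left,
                right_flank=right_src,
                tsd=locus.tsd_seq or "",
                integrated_left=integ_l,
                integrated_right=integ_r,
                empty=empty,
                junction_offsets=offsets,
                reliable=reliable,
                note=note,
            )
        )
    return assays


def _probe_cores(assay: JunctionAssay, min_overhang: int):
    """(allele, core) pairs: junction-centred subsequences of length
    2*min_overhang."""
    cores = []
    probes = {
        "integrated_left": assay.integrated_left,
        "integrated_right": assay.integrated_right,
        "empty": assay.empty,
    }
    for name, probe in probes.items():
        if probe is None or name not in assay.junction_offsets:
            continue
        j = assay.junction_offsets[name]
        if j - min_overhang < 0 or j + min_overhang > len(probe):
            continue
        allele = "empty" if name == "empty" else "integrated"
        cores.append((allele, probe[j - min_overhang : j + min_overhang]))
    return cores


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        path = str(reads)
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
        for rec in SeqIO.parse(path, fmt):
            yield rec.id, str(rec.seq).upper()
        return
    for r in reads:
        if hasattr(r, "seq"):
            yield r.id, str(r.seq).upper()
        else:
            name, seq = r
            yield name, seq.upper()


def genotype_sample(
    assays: list[JunctionAssay],
    reads,
    sample_id: str = "sample",
    min_overhang: int = 20,
    min_support: int = 2,
    max_mismatch: int = 1,
) -> list[JunctionGenotype]:
    """Presence/absence call per locus from junction-spanning reads.

    ``reads`` may be a FASTA/FASTQ path, SeqRecords, or (name, seq) pairs.
    States: present (only integrated junctions supported), absent (only the
    empty junction), both (heterozygous/mixed), no_data (neither allele
    reaches ``min_support``).
    """
    half = min_overhang
    # exact-half seeding: with <=1 mismatch in a 2*half core, one half is exact
    index: dict[str, list[tuple[int, str, str, int]]] = {}
    cores_per_assay: list[list[tuple[str, str]]] = []
    for ai, assay in enumerate(assays):
        cores = _probe_cores(assay, min_overhang)
        cores_per_assay.append(cores)
        for ci, (allele, core) in enumerate(cores):
            for orient, cseq in (("+", core), ("-", revcomp(core))):
                for hoff in (0, half):
                    index.setdefault(cseq[hoff : hoff + half], []).append(
                        (ai, allele, orient, hoff, cseq)
                    )

    support: dict[int, dict[str, set[str]]] = {
        ai: {"integrated": set(), "empty": set()} for ai in range(len(assays))
    }
    for name, seq in _iter_reads(reads):
        L = len(seq)
        if L < 2 * half:
            continue
        for pos in range(0, L - half + 1):
            entries = index.get(seq[pos : pos + half])
            if not entries:
                continue
            for ai, allele, orient, hoff, cseq in entries:
                start = pos - hoff
                if start < 0 or start + 2 * half > L:
                    continue
                window = seq[start : start + 2 * half]
                mm = sum(a != b for a, b in zip(window, cseq))
                if mm <= max_mismatch:
                    support[ai][allele].add(name)

    out = []
    for ai, assay in enumerate(assays):
        ni = len(support[ai]["integrated"])
        ne = len(support[ai]["empty"])
        if ni >= min_support and ne >= min_support:
            state = "both"
        elif ni >= min_support:
            state = "present"
        elif ne >= min_support:
            state = "absent"
        else:
            state = "no_data"
        out.append(JunctionGenotype(assay.locus_id, sample_id, state, ni, ne))
    return out


def _match_positions(template: str, probe: str, max_mismatch: int) -> list[int]:
    m = len(probe)
    out = []
    for i in range(len(template) - m + 1):
        seg = template[i : i + m]
        if max_mismatch == 0:
            if seg == probe:
                out.append(i)
        else:
            mm = 0
            for a, b in zip(seg, probe):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            if mm <= max_mismatch:
                out.append(i)
    return out


def in_silico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
    max_product: int = 2000,
) -> list[int]:
    """Product lengths of all primer pairings on either strand.

    A product spans a forward-primer site to a downstream reverse-complement
    site of the reverse primer, inclusive of both primers; both template
    orientations are searched and duplicate lengths from palindromic layouts
    are reported per pairing.
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    t = template.upper()
    products: list[int] = []
    for seq in (t, revcomp(t)):
        fpos = _match_positions(seq, fwd_primer.upper(), max_mismatch)
        rpos = _match_positions(seq, revcomp(rev_primer.upper()), max_mismatch)
        for f in fpos:
            for r in rpos:
                end = r + len(rev_primer)
                if end > f:
                    length = end - f
                    if length <= max_product:
                        products.append(length)
    return sorted(products)
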