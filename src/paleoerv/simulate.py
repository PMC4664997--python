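"""Synthetic genomes with planted ERV insertions and full ground truth.

The simulator emulates the genomic footprint of a gammaretroviral germline
invasion: proviruses with the canonical LTR-gag-pro-pol-env-LTR layout whose
two LTRs are identical at integration, 4-5 bp target-site duplications
(TSDs), a tRNA primer-binding site just inside the 5' LTR, a polypurine
tract before the 3' LTR, solo LTRs left by LTR-LTR recombination, two LTR
sequence subgroups (A/B) with diagnostic differences, optionally one
recombinant A/B mosaic LTR, assembly gaps (N runs), and insertion
presence/absence polymorphism across samples.

Post-insertional decay is a K2P-style substitution process at a host rate
(default 0.0015 subs/site/Myr, a published rate for bears) with CpG sites
hypermutable (default 10x, applied to both positions of a CpG as read from
the starting sequence).  Each LTR of a pair mutates independently, so the
expected pairwise divergence of a pair of age T is 2·rate·T.

Every planted feature is described by a :class:`TruthRecord`, the ground
truth against which mining, annotation, subgroup assignment, recombination
detection, dating and genotyping are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import ceil, log10
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA, TRANSITION, cpg_mask, random_dna, revcomp

__all__ = [
    "SimConfig",
    "TruthRecord",
    "Ancestor",
    "Simulation",
    "PlacementError",
    "mutate_sequence",
    "mutate_ltr_pair",
    "simulate_invasion",
    "simulate_reads",
    "haplotype_genome",
    "load_trna_library",
]

GENES = ("gag", "pro", "pol", "env")
# amino-acid length proportions for a ~6.9 kb internal region
_GENE_AA = {"gag": 430, "pro": 250, "pol": 560, "env": 420}
_PPT = "AGGAAGGGGGGA"  # polypurine tract ahead of the 3' LTR

_AA = "ARNDCQEGHILKMFPSTWYV"


class PlacementError(RuntimeError):
    """An insertion could not be placed without overlap on its scaffold."""


def load_trna_library(path=None) -> dict[str, str]:
    """Named tRNA 3'-end sequences (bundled synthetic library by default)."""
    if path is None:
        ref = resources.files("paleoerv.data") / "trna_3ends_synthetic.fasta"
        with ref.open() as fh:
            recs = list(SeqIO.parse(fh, "fasta"))
    else:
        recs = list(SeqIO.parse(str(path), "fasta"))
    return {r.id: str(r.seq).upper() for r in recs}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated invasion.

    Defaults mirror the reported polar-bear UrsusERV landscape: 4 proviruses
    (ages 0.625, 2.1875, 0 and an undatable recombinant-flanked one) plus 15
    solo LTRs, 23 planted LTRs in total (12 subgroup A, 10 subgroup B, 1 A/B
    recombinant), ~7.9 kb proviruses with 500 bp LTRs and 4 bp TSDs.
    """

    seed: int
    host_rate: float = 0.0015  # substitutions/site/Myr
    cpg_factor: float = 10.0
    ltr_length: int = 500
    internal_length: int = 6900  # provirus ~= 7900 bp
    tsd_length: int = 4
    n_proviruses: int = 4
    n_solo_ltrs: int = 15
    recombinant: bool = True
    recomb_breakpoint: int = 200  # 0-based LTR position where template B ends
    subgroup_div: float = 0.02
    provirus_ages: Optional[tuple[float, ...]] = None
    solo_age_range: tuple[float, float] = (0.5, 3.5)
    provirus_scaffold_len: int = 12000
    solo_scaffold_len: int = 2500
    n_empty_scaffolds: int = 2
    empty_scaffold_len: int = 5000
    gap_runs: tuple[tuple[str, int, int], ...] = ()  # (scaffold, start, length)
    samples: tuple[str, ...] = (
        "polar_1",
        "polar_2",
        "polar_3",
        "brown_1",
        "brown_2",
        "black_1",
    )
    ts_fraction: float = 2.0 / 3.0  # transitions:transversions 2:1

    def __post_init__(self) -> None:
        if self.host_rate < 0 or self.cpg_factor < 0:
            raise ValueError("rates must be non-negative")
        if self.ltr_length <= 0 or self.internal_length <= 0:
            raise ValueError("lengths must be positive")
        if self.tsd_length not in (4, 5):
            raise ValueError("tsd_length must be 4 or 5")
        if self.provirus_ages is not None and len(self.provirus_ages) != self.n_proviruses:
            raise ValueError("provirus_ages must match n_proviruses")
        if self.recombinant and not (0 < self.recomb_breakpoint < self.ltr_length):
            raise ValueError("recomb_breakpoint outside LTR")


@dataclass
class TruthRecord:
    """Ground truth for one planted feature (0-based half-open coordinates)."""

    feature_id: str
    kind: str  # provirus | solo_ltr
    chrom: str
    start: int
    end: int
    strand: str
    tsd_seq: str
    ltr_subgroup: str  # A | B | recombinant
    recomb_breakpoint: Optional[int]  # 1-based first LTR column from 2nd template
    true_age_myr: float
    present_in: frozenset[str]
    ltr5_interval: Optional[tuple[int, int]] = None
    ltr3_interval: Optional[tuple[int, int]] = None
    genes: dict = field(default_factory=dict)  # gene -> (start, end) absolute

    def __post_init__(self) -> None:
        if (self.recomb_breakpoint is not None) != (self.ltr_subgroup == "recombinant"):
            raise ValueError("recomb_breakpoint set iff subgroup is recombinant")


@dataclass
class Ancestor:
    """The ancestral (time-zero) element the invasion descended from."""

    provirus: str  # full LTR-internal-LTR sequence (subgroup-A LTRs)
    ltr_a: str
    ltr_b: str
    internal: str
    proteins: dict[str, str]  # gene -> amino-acid sequence
    gene_intervals: dict[str, tuple[int, int]]  # within provirus
    pbs_trna: str


@dataclass
class Simulation:
    genome: dict[str, str]
    truth: list[TruthRecord]
    ancestor: Ancestor
    config: SimConfig


# ---------------------------------------------------------------------------
# mutation process


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mutate_sequence(
    seq: str,
    expected_subs: float,
    cpg_factor: float,
    rng,
    ts_fraction: float = 2.0 / 3.0,
) -> str:
    """Apply one lineage of substitutions: per-site probability ``expected_subs``
    (clipped at 0.95), multiplied by ``cpg_factor`` at CpG sites of the input."""
    if expected_subs < 0:
        raise ValueError("expected_subs must be >= 0")
    rng = _as_rng(rng)
    arr = np.array(list(seq.upper()))
    p = np.full(len(arr), expected_subs)
    p[cpg_mask(seq)] *= cpg_factor
    np.clip(p, 0.0, 0.95, out=p)
    valid = np.isin(arr, list(DNA))
    hit = (rng.random(len(arr)) < p) & valid
    idx = np.flatnonzero(hit)
    if idx.size:
        is_ts = rng.random(idx.size) < ts_fraction
        pick = rng.integers(0, 2, size=idx.size)
        for j, i in enumerate(idx):
            base = arr[i]
            if is_ts[j]:
                arr[i] = TRANSITION[base]
            else:
                tv = [b for b in DNA if b != base and b != TRANSITION[base]]
                arr[i] = tv[pick[j]]
    return "".join(arr)


def mutate_ltr_pair(
    ltr: str,
    age_myr: float,
    rate: float = 0.0015,
    cpg_factor: float = 10.0,
    seed=0,
    ts_fraction: float = 2.0 / 3.0,
) -> tuple[str, str]:
    """Two independent copies of ``ltr`` after ``age_myr`` of neutral decay.

    Each copy receives substitutions independently, so E[pairwise p-distance]
    = 2·rate·age at cpg_factor 1.  ``age_myr=0`` returns identical copies.
    """
    if age_myr < 0:
        raise ValueError("age must be >= 0")
    rng = _as_rng(seed)
    e = rate * age_myr
    ltr5 = mutate_sequence(ltr, e, cpg_factor, rng, ts_fraction)
    ltr3 = mutate_sequence(ltr, e, cpg_factor, rng, ts_fraction)
    return ltr5, ltr3


# ---------------------------------------------------------------------------
# ancestral element construction


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    table = standard_dna_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        codons = sorted(by_aa[aa])
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(
        np.array(list(_AA))[rng.integers(0, len(_AA), size=length - 1)]
    )


def _build_ancestor(cfg: SimConfig, rng: np.random.Generator) -> Ancestor:
    trna = load_trna_library()
    pbs = revcomp(trna["tRNA-Pro"])

    # gene lengths scaled to the configured internal length
    overhead = len(pbs) + len(_PPT) + 5 * 30  # PBS, PPT, minimal spacers
    budget_nt = cfg.internal_length - overhead
    total_aa = sum(_GENE_AA.values())
    if budget_nt < 3 * 4 * 30:
        raise ValueError("internal_length too small to host four genes")
    aa_len = {
        g: max(30, int(budget_nt // 3 * (_GENE_AA[g] / total_aa))) for g in GENES
    }
    proteins = {g: _random_protein(rng, aa_len[g]) for g in GENES}
    cds = {g: _back_translate(proteins[g], rng) for g in GENES}

    used = len(pbs) + len(_PPT) + sum(len(c) for c in cds.values())
    pad = cfg.internal_length - used
    if pad < 0:
        raise ValueError("internal_length too small")
    # leader gets the bulk of the padding; small inter-gene spacers
    spacer = [pad - 4 * (pad // 8)] + [pad // 8] * 3 + [pad // 8]

    parts = [pbs, random_dna(rng, spacer[0])]
    gene_intervals: dict[str, tuple[int, int]] = {}
    pos = sum(len(x) for x in parts)
    for i, g in enumerate(GENES):
        gene_intervals[g] = (pos, pos + len(cds[g]))
        parts.append(cds[g])
        pos += len(cds[g])
        if i < 3:
            parts.append(random_dna(rng, spacer[i + 1]))
            pos += spacer[i + 1]
    tail = cfg.internal_length - pos - len(_PPT)
    parts.append(random_dna(rng, tail))
    parts.append(_PPT)
    internal = "".join(parts)
    assert len(internal) == cfg.internal_length

    ltr_a = list(random_dna(rng, cfg.ltr_length))
    ltr_a[0:2] = "TG"  # canonical retroviral LTR termini
    ltr_a[-2:] = "CA"
    ltr_a = "".join(ltr_a)
    # subgroup B: diagnostic differences at ~subgroup_div of sites
    b = list(ltr_a)
    for i in range(2, cfg.ltr_length - 2):
        if rng.random() < cfg.subgroup_div:
            alts = [x for x in DNA if x != b[i]]
            b[i] = alts[rng.integers(0, 3)]
    ltr_b = "".join(b)

    # gene coordinates within the full provirus (offset by the 5' LTR)
    gene_intervals = {
        g: (s + cfg.ltr_length, e + cfg.ltr_length) for g, (s, e) in gene_intervals.items()
    }
    provirus = ltr_a + internal + ltr_a
    return Ancestor(
        provirus=provirus,
        ltr_a=ltr_a,
        ltr_b=ltr_b,
        internal=internal,
        proteins=proteins,
        gene_intervals=gene_intervals,
        pbs_trna="tRNA-Pro",
    )


# ---------------------------------------------------------------------------
# invasion


def _default_provirus_plan(cfg: SimConfig):
    """(subgroup, age, recombinant_3ltr) per provirus; mirrors the four
    reported proviruses: two A-flanked (one young), one B-flanked, one with a
    recombinant 3' LTR that cannot be dated."""
    if cfg.provirus_ages is not None:
        ages = list(cfg.provirus_ages)
    else:
        ages = [0.625, 2.1875, 0.0, 1.5][: cfg.n_proviruses]
        while len(ages) < cfg.n_proviruses:
            ages.append(1.0)
    plan = []
    for i in range(cfg.n_proviruses):
        sub = "B" if i == 1 else "A"
        rec = cfg.recombinant and i == min(3, cfg.n_proviruses - 1)
        plan.append((sub, ages[i], rec))
    return plan


def _solo_subgroups(cfg: SimConfig) -> list[str]:
    # With the default plan (5 proviral A, 2 proviral B, 1 recombinant) this
    # yields totals of 12 A and 10 B among 23 LTRs.
    n = cfg.n_solo_ltrs
    n_a = min(7, n) if cfg.n_proviruses >= 4 else (n + 1) // 2
    return ["A"] * n_a + ["B"] * (n - n_a)


def _place(rng: np.random.Generator, scaffold_len: int, elem_len: int, margin: int,
           occupied: list[tuple[int, int]]) -> int:
    lo, hi = margin, scaffold_len - elem_len - margin
    if hi < lo:
        raise PlacementError(
            f"scaffold of {scaffold_len} bp cannot host a {elem_len} bp insertion"
        )
    for _ in range(1000):
        p = int(rng.integers(lo, hi + 1))
        if all(p + elem_len <= s or p >= e for s, e in occupied):
            return p
    raise PlacementError("no non-overlapping placement found")


def simulate_invasion(config: SimConfig) -> Simulation:
    """Plant proviruses and solo LTRs into random host scaffolds.

    Each insertion gets its own scaffold (proviruses first, then solo LTRs,
    then empty decoy scaffolds), an exact TSD duplication, and independent
    post-insertional decay of its two LTRs and internal region according to
    its true age.  Fully deterministic in ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    anc = _build_ancestor(cfg, rng)
    k = cfg.tsd_length

    genome: dict[str, str] = {}
    truth: list[TruthRecord] = []
    margin = 200

    plan = _default_provirus_plan(cfg)
    solo_subs = _solo_subgroups(cfg)
    presence = _presence_table(cfg, plan, solo_subs, rng)

    for i, (sub, age, rec) in enumerate(plan):
        chrom = f"scaffold_{i + 1}"
        host = random_dna(rng, cfg.provirus_scaffold_len)
        template5 = anc.ltr_a if sub == "A" else anc.ltr_b
        if rec:
            bp = cfg.recomb_breakpoint
            template3 = anc.ltr_b[:bp] + anc.ltr_a[bp:]
        else:
            template3 = template5
        e = cfg.host_rate * age
        ltr5 = mutate_sequence(template5, e, cfg.cpg_factor, rng, cfg.ts_fraction)
        ltr3 = mutate_sequence(template3, e, cfg.cpg_factor, rng, cfg.ts_fraction)
        internal = mutate_sequence(anc.internal, e, cfg.cpg_factor, rng, cfg.ts_fraction)
        element = ltr5 + internal + ltr3

        pos = _place(rng, len(host), len(element) + k, margin, [])
        tsd = host[pos : pos + k]
        seq = host[: pos + k] + element + host[pos:]
        start = pos + k
        end = start + len(element)
        genome[chrom] = seq
        L = cfg.ltr_length
        truth.append(
            TruthRecord(
                feature_id=f"provirus_{i + 1}",
                kind="provirus",
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                tsd_seq=tsd,
                ltr_subgroup="recombinant" if rec else sub,
                recomb_breakpoint=cfg.recomb_breakpoint + 1 if rec else None,
                true_age_myr=age,
                present_in=presence[f"provirus_{i + 1}"],
                ltr5_interval=(start, start + L),
                ltr3_interval=(end - L, end),
                genes={
                    g: (start + s, start + e2) for g, (s, e2) in anc.gene_intervals.items()
                },
            )
        )

    lo, hi = cfg.solo_age_range
    for j in range(cfg.n_solo_ltrs):
        chrom = f"scaffold_solo_{j + 1}"
        host = random_dna(rng, cfg.solo_scaffold_len)
        sub = solo_subs[j]
        template = anc.ltr_a if sub == "A" else anc.ltr_b
        age = float(rng.uniform(lo, hi))
        ltr = mutate_sequence(template, cfg.host_rate * age, cfg.cpg_factor, rng,
                              cfg.ts_fraction)
        pos = _place(rng, len(host), len(ltr) + k, margin, [])
        tsd = host[pos : pos + k]
        seq = host[: pos + k] + ltr + host[pos:]
        start, end = pos + k, pos + k + len(ltr)
        genome[chrom] = seq
        truth.append(
            TruthRecord(
                feature_id=f"solo_{j + 1}",
                kind="solo_ltr",
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                tsd_seq=tsd,
                ltr_subgroup=sub,
                recomb_breakpoint=None,
                true_age_myr=age,
                present_in=presence[f"solo_{j + 1}"],
                ltr5_interval=(start, end),
            )
        )

    for m in range(cfg.n_empty_scaffolds):
        genome[f"scaffold_empty_{m + 1}"] = random_dna(rng, cfg.empty_scaffold_len)

    for chrom, start, length in cfg.gap_runs:
        s = genome[chrom]
        if start < 0 or start + length > len(s):
            raise ValueError(f"gap run outside {chrom}")
        genome[chrom] = s[:start] + "N" * length + s[start + length :]

    return Simulation(genome=genome, truth=truth, ancestor=anc, config=cfg)


def _presence_table(cfg, plan, solo_subs, rng) -> dict[str, frozenset[str]]:
    """Per-feature sample presence.  Polar samples carry everything; the
    young (age 0) provirus is polar-specific; one older provirus is
    polymorphic among brown bears; the black-bear sample carries none of the
    polar-bear insertion sites (flanks uninterrupted)."""
    polar = tuple(s for s in cfg.samples if s.startswith("polar"))
    brown = tuple(s for s in cfg.samples if s.startswith("brown"))
    others = tuple(
        s for s in cfg.samples if not s.startswith(("polar", "brown", "black"))
    )
    table: dict[str, frozenset[str]] = {}
    for i, (_sub, age, _rec) in enumerate(plan):
        fid = f"provirus_{i + 1}"
        present = set(polar) | set(others)
        if age > 0:
            present |= set(brown)
        if i == 0 and len(brown) > 0:  # polymorphic: first brown lacks it
            present.discard(brown[0])
        table[fid] = frozenset(present)
    for j in range(len(solo_subs)):
        present = set(polar) | set(others)
        for b in brown:
            if rng.random() < 0.8:
                present.add(b)
        table[f"solo_{j + 1}"] = frozenset(present)
    return table


def haplotype_genome(sim: Simulation, sample_id: str) -> dict[str, str]:
    """Genome of one sample: absent insertions reverted to the empty
    pre-integration site (element plus ONE TSD copy spliced out)."""
    if sample_id not in sim.config.samples:
        raise KeyError(sample_id)
    genome = dict(sim.genome)
    by_chrom: dict[str, list[TruthRecord]] = {}
    for t in sim.truth:
        if sample_id not in t.present_in:
            by_chrom.setdefault(t.chrom, []).append(t)
    k = sim.config.tsd_length
    for chrom, recs in by_chrom.items():
        seq = genome[chrom]
        for t in sorted(recs, key=lambda r: -r.start):
            seq = seq[: t.start] + seq[t.end + k :]
        genome[chrom] = seq
    return genome


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: dict[str, str],
    read_length: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.005,
    seed: int = 0,
    sample_id: str = "sample",
) -> list[SeqRecord]:
    """Uniform single-end reads from both strands at the requested fold
    coverage, with i.i.d. substitution errors and flat Phred qualities."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    chroms = sorted(genome)
    usable = [c for c in chroms if len(genome[c]) >= read_length]
    if not usable:
        raise ValueError("read_length exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    total = sum(len(genome[c]) for c in usable)
    n_reads = int(ceil(coverage * total / read_length))
    weights = np.array([len(genome[c]) - read_length + 1 for c in usable], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(usable), size=n_reads, p=weights)
    qual = 40 if error_rate <= 0 else min(40, int(round(-10 * log10(error_rate))))
    records = []
    for r in range(n_reads):
        c = usable[which[r]]
        seq = genome[c]
        pos = int(rng.integers(0, len(seq) - read_length + 1))
        frag = seq[pos : pos + read_length]
        strand = "+"
        if rng.random() < 0.5:
            frag = revcomp(frag)
            strand = "-"
        if error_rate > 0:
            arr = np.array(list(frag))
            hit = np.flatnonzero(
                (rng.random(read_length) < error_rate) & np.isin(arr, list(DNA))
            )
            for i in hit:
                alts = [b for b in DNA if b != arr[i]]
                arr[i] = alts[rng.integers(0, 3)]
            frag = "".join(arr)
        rec = SeqRecord(
            Seq(frag),
            id=f"{sample_id}_read_{r}",
            description=f"{c}:{pos}:{strand}",
        )
        rec.letter_annotations["phred_quality"] = [qual] * read_length
        records.append(rec)
    return records
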