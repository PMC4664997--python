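"""End-to-end orchestration: mine -> annotate -> groups -> recombination ->
date -> genotype, with report tables in the style of an ERV characterisation
paper (recombination savings table, TSD table, LTR-divergence dating table),
a GFF3 of loci, and a JSON run manifest.

All stages are importable on their own; this module only wires them
together and owns serialisation.  Reports print 1-based inclusive
coordinates; GFF3/BED follow their own conventions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import detect_tsd, reconstruct_putein
from .consensus import assign_subgroups, mafft_align, majority_consensus
from .dating import RecombinantLtrError, date_provirus
from .genotyping import build_assays, genotype_sample
from .io import write_fasta, write_gff3, write_truth
from .mining import classify_loci, find_candidate_loci, refine_boundaries
from .recombination import savings_scan
from .simulate import SimConfig, haplotype_genome, simulate_invasion, simulate_reads

log = logging.getLogger("paleoerv")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Serialisable configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "paleoerv_run"
    genome_fasta: str | None = None  # None -> simulate
    query_fasta: str | None = None
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    min_identity: float = 80.0
    min_length: int = 200
    seed_k: int = 12
    flank: int = 1000
    ltr_min: int = 300
    ltr_max: int = 1200
    min_ltr_identity: float = 85.0
    alpha: float = 1.0
    n_permutations: int = 1000
    rate: float = 0.0015
    exclude_cpg: bool = True
    recomb_p_threshold: float = 0.05
    genotype_samples: tuple[str, ...] = ()
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.005
    truth_aware: bool = False
    puteins: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "genotype_samples" in d:
            d["genotype_samples"] = tuple(d["genotype_samples"])
        return cls(**d)


@dataclass
class PipelineResult:
    loci: list
    counts: object
    assignment: object
    recomb_table: pd.DataFrame
    tsd_table: pd.DataFrame
    dating_table: pd.DataFrame
    genotype_table: pd.DataFrame | None
    truth_summary: dict | None
    outdir: Path


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> PipelineResult:
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    sim = None
    if cfg.genome_fasta is None:
        _stage("simulate")
        sim = simulate_invasion(SimConfig(seed=cfg.seed, **cfg.sim))
        genome = sim.genome
        queries = {"erv_consensus": sim.ancestor.provirus}
        query_ltr = sim.ancestor.ltr_a
        write_fasta(genome, out / "genome.fasta")
        write_truth(sim.truth, out / "truth.bed", out / "truth.json")
    else:
        from .io import read_fasta

        genome = read_fasta(cfg.genome_fasta)
        if cfg.query_fasta is None:
            raise ValueError("query_fasta required with genome_fasta")
        queries = read_fasta(cfg.query_fasta)
        q0 = queries[sorted(queries)[0]]
        query_ltr = q0[: cfg.ltr_max]

    _stage("mine")
    hits = find_candidate_loci(
        genome,
        queries,
        min_identity=cfg.min_identity,
        min_length=cfg.min_length,
        seed_k=cfg.seed_k,
    )
    loci = []
    for i, h in enumerate(hits):
        loci.append(
            refine_boundaries(
                genome,
                h,
                flank=cfg.flank,
                ltr_min=cfg.ltr_min,
                ltr_max=cfg.ltr_max,
                min_ltr_identity=cfg.min_ltr_identity,
                query_ltr=query_ltr,
                locus_id=f"locus_{i + 1}_{h.chrom}",
            )
        )
    counts = classify_loci(loci)
    write_gff3(loci, out / "loci.gff3")

    _stage("annotate")
    tsd_rows = []
    for locus in loci:
        call = detect_tsd(genome, locus)
        locus.tsd_seq = call.tsd_seq
        tsd_rows.append(
            {
                "Locus": locus.locus_id,
                "Scaffold": locus.chrom,
                "TSD Sequence": f"{call.tsd_seq}/{call.tsd_seq}"
                if call.tsd_seq
                else "N/A",
            }
        )
    tsd_table = pd.DataFrame(tsd_rows)

    putein_rows = []
    if cfg.puteins and sim is not None:
        for locus in (l for l in loci if l.kind == "provirus"):
            locus_seq = genome[locus.chrom][locus.start : locus.end]
            for gene, prot in sim.ancestor.proteins.items():
                p = reconstruct_putein(locus_seq, prot, gene=gene)
                putein_rows.append(
                    {
                        "Locus": locus.locus_id,
                        "Gene": gene,
                        "Frameshifts": p.frameshift_count,
                        "Identity %": round(p.percent_identity, 1),
                    }
                )

    _stage("groups")
    ltr_seqs: dict[str, str] = {}
    for locus in loci:
        seq = genome[locus.chrom]
        if locus.kind == "provirus":
            a, b = locus.ltr5_interval, locus.ltr3_interval
            ltr_seqs[f"{locus.locus_id}_LTR5"] = seq[a[0] : a[1]]
            ltr_seqs[f"{locus.locus_id}_LTR3"] = seq[b[0] : b[1]]
        elif locus.kind == "solo_ltr":
            ltr_seqs[f"{locus.locus_id}_solo"] = seq[locus.start : locus.end]
    if len(ltr_seqs) >= 4:
        msa = mafft_align(ltr_seqs)
        cons = majority_consensus(msa)
        write_fasta({"ltr_consensus": cons}, out / "ltr_consensus.fasta")
        msa.write_fasta(out / "ltr_alignment.fasta")
        assignment = assign_subgroups(msa)
    else:
        msa = None
        assignment = None

    _stage("recombination")
    rec_rows = []
    if msa is not None and msa.n_seqs >= 3:
        for name in msa.names:
            res = savings_scan(
                msa,
                name,
                alpha=cfg.alpha,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed,
            )
            if res.savings > 0 and res.p_value <= cfg.recomb_p_threshold:
                rec_rows.append(
                    {
                        "Sequence": name,
                        "Start": res.start,
                        "End": res.end,
                        "Savings": int(res.savings),
                        "Seq pv": f"{res.p_value:.6f}",
                    }
                )
    recomb_table = pd.DataFrame(rec_rows, columns=["Sequence", "Start", "End", "Savings", "Seq pv"])
    flagged = set(r["Sequence"] for r in rec_rows)

    _stage("date")
    date_rows = []
    for locus in (l for l in loci if l.kind == "provirus"):
        seq = genome[locus.chrom]
        a, b = locus.ltr5_interval, locus.ltr3_interval
        from .dating import align_pair

        ltr5, ltr3 = align_pair(seq[a[0] : a[1]], seq[b[0] : b[1]])
        is_rec = f"{locus.locus_id}_LTR3" in flagged or f"{locus.locus_id}_LTR5" in flagged
        if assignment is not None:
            for suffix in ("LTR5", "LTR3"):
                if assignment.labels.get(f"{locus.locus_id}_{suffix}") == "recombinant":
                    is_rec = True
        row = {
            "Locus": locus.locus_id,
            "5' LTR Location": f"{a[0] + 1:,}–{a[1]:,}",
            "3' LTR Location": f"{b[0] + 1:,}–{b[1]:,}",
        }
        try:
            est = date_provirus(
                ltr5,
                ltr3,
                rate=cfg.rate,
                exclude_cpg=cfg.exclude_cpg,
                seed=cfg.seed,
                recombinant=is_rec,
            )
            row["Overall Mean K2P Distance"] = round(est.D, 3)
            row["Age Estimation Mya"] = round(est.age_myr, 4)
        except RecombinantLtrError:
            row["Overall Mean K2P Distance"] = "ND"
            row["Age Estimation Mya"] = "ND"
        date_rows.append(row)
    dating_table = pd.DataFrame(date_rows)

    genotype_table = None
    if cfg.genotype_samples and sim is not None:
        _stage("genotype")
        assays = build_assays(genome, loci)
        rows = {}
        for si, s in enumerate(cfg.genotype_samples):
            hap = haplotype_genome(sim, s)
            reads = simulate_reads(
                hap,
                read_length=cfg.read_length,
                coverage=cfg.coverage,
                error_rate=cfg.error_rate,
                seed=cfg.seed * 1009 + si,
                sample_id=s,
            )
            for g in genotype_sample(assays, reads, sample_id=s):
                rows.setdefault(g.locus_id, {})[s] = g.state
        genotype_table = pd.DataFrame(rows).T.sort_index()

    truth_summary = None
    if cfg.truth_aware and sim is not None:
        truth_summary = _score_against_truth(sim, loci, assignment)
        (out / "truth_summary.json").write_text(json.dumps(truth_summary, indent=1))

    recomb_table.to_csv(out / "table_recombination.tsv", sep="\t", index=False)
    tsd_table.to_csv(out / "table_tsd.tsv", sep="\t", index=False)
    dating_table.to_csv(out / "table_dating.tsv", sep="\t", index=False)
    if putein_rows:
        pd.DataFrame(putein_rows).to_csv(out / "table_puteins.tsv", sep="\t", index=False)
    if genotype_table is not None:
        genotype_table.to_csv(out / "genotype_matrix.tsv", sep="\t")
    manifest = {
        "package": "paleoerv",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.to_json()),
        "n_loci": len(loci),
        "counts": dataclasses.asdict(counts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        loci=loci,
        counts=counts,
        assignment=assignment,
        recomb_table=recomb_table,
        tsd_table=tsd_table,
        dating_table=dating_table,
        genotype_table=genotype_table,
        truth_summary=truth_summary,
        outdir=out,
    )


def _overlap(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _score_against_truth(sim, loci, assignment) -> dict:
    """Recall/precision of mining plus boundary accuracy and subgroup
    concordance against the simulator's truth records."""
    matched = {}
    used = set()
    for t in sim.truth:
        best = None
        for i, l in enumerate(loci):
            if i in used or l.chrom != t.chrom:
                continue
            ov = _overlap((t.start, t.end), (l.start, l.end))
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, i)
        if best:
            used.add(best[1])
            matched[t.feature_id] = best[1]
    n_truth = len(sim.truth)
    recall = len(matched) / n_truth if n_truth else 0.0
    precision = len(matched) / len(loci) if loci else 1.0
    berr = {
        fid: abs(loci[i].start - t.start) + abs(loci[i].end - t.end)
        for t in sim.truth
        for fid, i in ((t.feature_id, matched.get(t.feature_id)),)
        if i is not None
    }
    sub_ok = sub_tot = 0
    if assignment is not None:
        for t in sim.truth:
            i = matched.get(t.feature_id)
            if i is None:
                continue
            locus = loci[i]
            pairs = []
            if t.kind == "provirus":
                pairs = [
                    (f"{locus.locus_id}_LTR5", t.ltr_subgroup if t.ltr_subgroup != "recombinant" else "A"),
                    (f"{locus.locus_id}_LTR3", "recombinant" if t.ltr_subgroup == "recombinant" else t.ltr_subgroup),
                ]
            else:
                pairs = [(f"{locus.locus_id}_solo", t.ltr_subgroup)]
            for name, want in pairs:
                if name in assignment.labels:
                    sub_tot += 1
                    sub_ok += assignment.labels[name] == want
    return {
        "recall": recall,
        "precision": precision,
        "boundary_error_bp": berr,
        "max_boundary_error_bp": max(berr.values()) if berr else None,
        "subgroup_correct": sub_ok,
        "subgroup_total": sub_tot,
    }
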