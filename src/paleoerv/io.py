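"""Readers/writers for the package's external formats (FASTA/FASTQ via
biopython; GFF3/BED/JSON emitted directly — coordinates follow each format's
convention: BED/GFF intervals as 0-based half-open / 1-based inclusive)."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_truth(truth, path_bed, path_json) -> None:
    """Ground truth as BED6 (0-based half-open) plus a full JSON dump."""
    with open(path_bed, "w") as fh:
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.feature_id}\t0\t{t.strand}\n"
            )
    payload = []
    for t in truth:
        payload.append(
            {
                "feature_id": t.feature_id,
                "kind": t.kind,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "tsd_seq": t.tsd_seq,
                "ltr_subgroup": t.ltr_subgroup,
                "recomb_breakpoint": t.recomb_breakpoint,
                "true_age_myr": t.true_age_myr,
                "present_in": sorted(t.present_in),
                "ltr5_interval": t.ltr5_interval,
                "ltr3_interval": t.ltr3_interval,
                "genes": {g: list(iv) for g, iv in t.genes.items()},
            }
        )
    Path(path_json).write_text(json.dumps(payload, indent=1))


def write_gff3(loci, path, source: str = "paleoerv") -> None:
    """Loci as GFF3: provirus/solo_LTR/partial features with child LTR and
    assembly_gap features (1-based inclusive per the GFF spec)."""
    type_map = {"provirus": "provirus", "solo_ltr": "solo_LTR", "partial": "partial"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            attrs = f"ID={locus.locus_id}"
            if locus.tsd_seq:
                attrs += f";tsd={locus.tsd_seq}"
            if locus.notes:
                attrs += f";note={locus.notes.replace(';', ',')}"
            fh.write(
                f"{locus.chrom}\t{source}\t{type_map[locus.kind]}\t"
                f"{locus.start + 1}\t{locus.end}\t.\t{locus.strand}\t.\t{attrs}\n"
            )
            for tag, iv in (("five_prime", locus.ltr5_interval),
                            ("three_prime", locus.ltr3_interval)):
                if iv is None:
                    continue
                if locus.kind == "solo_ltr" and tag == "three_prime":
                    continue
                fh.write(
                    f"{locus.chrom}\t{source}\tlong_terminal_repeat\t{iv[0] + 1}\t"
                    f"{iv[1]}\t.\t{locus.strand}\t.\t"
                    f"ID={locus.locus_id}_LTR_{tag};Parent={locus.locus_id}\n"
                )
            for gi, (a, b) in enumerate(locus.gap_intervals):
                fh.write(
                    f"{locus.chrom}\t{source}\tassembly_gap\t{a + 1}\t{b}\t.\t.\t.\t"
                    f"ID={locus.locus_id}_gap_{gi};Parent={locus.locus_id}\n"
                )
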