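"""TSD/PBS detection and frameshift-aware putein reconstruction."""

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

import paleoerv as pe
from paleoerv._seq import random_dna, revcomp
from paleoerv.simulate import load_trna_library


class _Locus:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end
        self.tsd_seq = None
        self.locus_id = f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------------------
# TSD


def _brute_tsd(gseq, s, e, k_min=4, k_max=6):
    """Independent scanner: longest exact duplication flanking [s, e)."""
    best = None
    for k in range(k_min, k_max + 1):
        if s - k < 0 or e + k > len(gseq):
            continue
        left, right = gseq[s - k : s], gseq[e : e + k]
        if left == right and "N" not in left:
            best = left
    return best


class TestDetectTsd:
    def test_exact_four_bp_duplication(self):
        g = {"c": "TTTTTTCATC" + "G" * 50 + "CATCTTTTTT"}
        call = pe.detect_tsd(g, _Locus("c", 10, 60))
        assert call.tsd_seq == "CATC"
        assert call.left_interval == (6, 10) and call.right_interval == (60, 64)

    def test_five_preferred_over_internal_four(self):
        g = {"c": "TTTTACTT" + "G" * 40 + "TACTTTTTT"}
        call = pe.detect_tsd(g, _Locus("c", 8, 48), k_min=4, k_max=6)
        assert call.tsd_seq == "TACTT"

    def test_no_duplication_returns_none_but_determinable(self):
        g = {"c": "ACGTACGTAA" + "G" * 40 + "CCTTCCTTAA"}
        call = pe.detect_tsd(g, _Locus("c", 10, 50))
        assert call.tsd_seq is None and call.determinable

    def test_contig_edge_not_determinable(self):
        g = {"c": "AC" + "G" * 40 + "ACGTACGTA"}
        call = pe.detect_tsd(g, _Locus("c", 2, 42))
        assert call.tsd_seq is None and not call.determinable

    def test_n_in_flank_not_determinable(self):
        g = {"c": "TTNTTT" + "G" * 40 + "TTTTTT"}
        call = pe.detect_tsd(g, _Locus("c", 6, 46))
        assert not call.determinable

    def test_agrees_with_brute_force_on_random_loci(self):
        rng = np.random.default_rng(12)
        gseq = random_dna(rng, 4000)
        for _ in range(1000):
            s = int(rng.integers(10, 3900))
            e = int(rng.integers(s + 10, min(s + 90, 3990)))
            g2 = gseq
            if rng.random() < 0.5:  # plant a duplication half the time
                k = int(rng.integers(4, 7))
                g2 = gseq[: e] + gseq[s - k : s] + gseq[e + k :]
            call = pe.detect_tsd({"c": g2}, _Locus("c", s, e))
            assert call.tsd_seq == _brute_tsd(g2, s, e)


# ---------------------------------------------------------------------------
# PBS


class TestDetectPbs:
    def setup_method(self):
        self.lib = load_trna_library()

    def test_exact_planted_pbs(self):
        rng = np.random.default_rng(1)
        ltr = random_dna(rng, 100)
        locus = ltr + revcomp(self.lib["tRNA-Pro"]) + random_dna(rng, 100)
        call = pe.detect_pbs(locus, ltr5_end=100, trna_library=self.lib)
        assert call.trna_name == "tRNA-Pro"
        assert call.mismatches == 0 and call.match_length == 18
        assert call.interval == (100, 118)

    def test_fewest_mismatches_wins(self):
        rng = np.random.default_rng(2)
        probe = revcomp(self.lib["tRNA-Pro"])
        one_mm = probe[:9] + ("A" if probe[9] != "A" else "C") + probe[10:]
        locus = random_dna(rng, 50) + one_mm + random_dna(rng, 50)
        lib = {
            "tRNA-Pro": self.lib["tRNA-Pro"],  # 1 mismatch to the window
            "tRNA-Lys": self.lib["tRNA-Lys"],  # unrelated
        }
        call = pe.detect_pbs(locus, ltr5_end=50, trna_library=lib)
        assert call.trna_name == "tRNA-Pro" and call.mismatches == 1

    def test_random_windows_give_no_call(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(1000):
            locus = random_dna(rng, 60)
            if pe.detect_pbs(locus, ltr5_end=10, trna_library=self.lib) is not None:
                hits += 1
        assert hits == 0

    def test_missing_ltr_raises(self):
        with pytest.raises(ValueError, match="5' LTR"):
            pe.detect_pbs("ACGT" * 30, ltr5_end=None)


# ---------------------------------------------------------------------------
# putein


def _oracle_putein_score(nt, ref, fs=-20.0, gp=-8.0, stop=-10.0):
    """Independent top-down search over the same move set as the DP.

    Frameshift codons (2 or 4 nt) score the best repair-compatible
    translation: any single-base completion of a 2-mer, any single-base
    deletion from a 4-mer."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(nt), len(ref)

    def aa_score(aa, r):
        return stop if aa == "*" else float(blosum[aa, r])

    def best_repair2(kmer, r):
        cands = {
            str(Seq(kmer[:pos] + x + kmer[pos:]).translate())
            for pos in range(3)
            for x in "ACGT"
        }
        return max(aa_score(aa, r) for aa in cands)

    def best_repair4(kmer, r):
        cands = {str(Seq(kmer[:d] + kmer[d + 1 :]).translate()) for d in range(4)}
        return max(aa_score(aa, r) for aa in cands)

    @lru_cache(maxsize=None)
    def best(i, j):
        if j == m:
            return 0.0
        opts = [best(i, j + 1) + gp]
        if i + 3 <= n:
            opts.append(best(i + 3, j + 1) + aa_score(str(Seq(nt[i : i + 3]).translate()), ref[j]))
        if i + 2 <= n:
            opts.append(best(i + 2, j + 1) + fs + best_repair2(nt[i : i + 2], ref[j]))
        if i + 4 <= n:
            opts.append(best(i + 4, j + 1) + fs + best_repair4(nt[i : i + 4], ref[j]))
        if i + 1 <= n:
            opts.append(best(i + 1, j) + fs)
        return max(opts)

    return max(best(i, 0) for i in range(n + 1))


def _back_translate_simple(protein):
    table = {
        "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
        "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
        "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
        "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    }
    return "".join(table[a] for a in protein)


class TestReconstructPutein:
    REF = "MKLVDEWAGHTRPFYQSINC"

    def test_exact_back_translation(self):
        nt = _back_translate_simple(self.REF)
        p = pe.reconstruct_putein(nt, self.REF)
        assert p.frameshift_count == 0
        assert p.percent_identity == 100.0
        assert p.sequence == self.REF

    def test_single_insertion_one_frameshift(self):
        nt = _back_translate_simple(self.REF)
        nt = nt[:31] + "G" + nt[31:]  # 1-nt insertion mid-gene
        p = pe.reconstruct_putein(nt, self.REF)
        assert p.frameshift_count == 1
        assert p.percent_identity == 100.0
        assert p.sequence == self.REF

    def test_two_separated_deletions_two_frameshifts(self):
        nt = _back_translate_simple(self.REF)
        nt = nt[:10] + nt[11:40] + nt[41:]  # two separated 1-nt deletions
        p = pe.reconstruct_putein(nt, self.REF)
        assert p.frameshift_count == 2

    def test_score_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(12):
            ref = "".join(rng.choice(list(aas), int(rng.integers(4, 9))))
            nt = list(_back_translate_simple(ref))
            # random decay: substitutions and small indels
            for _ in range(int(rng.integers(0, 4))):
                op = rng.random()
                pos = int(rng.integers(0, len(nt)))
                if op < 0.5:
                    nt[pos] = "ACGT"[rng.integers(0, 4)]
                elif op < 0.75 and len(nt) > 6:
                    del nt[pos]
                else:
                    nt.insert(pos, "ACGT"[rng.integers(0, 4)])
            nt = "".join(nt)
            p = pe.reconstruct_putein(nt, ref)
            oracle = _oracle_putein_score(nt, ref)
            assert p.score == pytest.approx(oracle, abs=1e-6)

    def test_frameshift_count_monotone_in_penalty(self):
        nt = _back_translate_simple(self.REF)
        nt = nt[:13] + nt[14:29] + "T" + nt[29:]
        counts = [
            pe.reconstruct_putein(nt, self.REF, frameshift_penalty=fp).frameshift_count
            for fp in (-5.0, -10.0, -20.0, -40.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            pe.reconstruct_putein("AC", self.REF)
        with pytest.raises(ValueError):
            pe.reconstruct_putein("ACGACG", "")

    def test_recovers_planted_gene_in_simulated_provirus(self, default_sim):
        sim = default_sim
        t = next(x for x in sim.truth if x.true_age_myr == 0.625)
        g = sim.genome[t.chrom]
        p = pe.reconstruct_putein(g[t.start : t.end], sim.ancestor.proteins["gag"],
                                  gene="gag")
        assert p.gene == "gag"
        assert p.frameshift_count == 0
        assert p.percent_identity > 95.0


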