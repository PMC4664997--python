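"""Junction presence/absence genotyping and in-silico PCR."""

import numpy as np
import pytest

import paleoerv as pe
from paleoerv._seq import random_dna, revcomp
from paleoerv.genotyping import build_assays, genotype_sample, in_silico_pcr


def _sim(seed, **kw):
    cfg = dict(
        n_proviruses=2,
        n_solo_ltrs=2,
        internal_length=2400,
        provirus_scaffold_len=7000,
        solo_scaffold_len=2000,
        n_empty_scaffolds=0,
        recombinant=False,
        provirus_ages=(1.0, 0.0),
    )
    cfg.update(kw)
    return pe.simulate_invasion(pe.SimConfig(seed=seed, **cfg))


def _truth_loci(sim):
    class L:
        pass

    out = []
    for t in sim.truth:
        l = L()
        l.chrom, l.start, l.end = t.chrom, t.start, t.end
        l.tsd_seq, l.locus_id = t.tsd_seq, t.feature_id
        out.append(l)
    return out


class TestBuildAssays:
    def test_empty_probe_reconstructs_preintegration_site(self):
        sim = _sim(2)
        assays = build_assays(sim.genome, _truth_loci(sim), flank_len=60)
        by_id = {a.locus_id: a for a in assays}
        for t in sim.truth:
            a = by_id[t.feature_id]
            g = sim.genome[t.chrom]
            k = len(t.tsd_seq)
            # round trip: re-inserting element + one TSD copy regenerates
            # the reference haplotype around the locus
            L = len(a.left_flank)
            rebuilt = a.empty[:L] + g[t.start : t.end + k] + a.empty[L:]
            assert rebuilt == g[t.start - L : t.end + k + len(a.right_flank)]
            # empty junction carries exactly one TSD copy
            assert a.empty[L - k : L] == t.tsd_seq
            hap = pe.haplotype_genome(sim, "black_1")
            assert a.empty in hap[t.chrom]

    def test_probes_are_reference_substrings(self):
        sim = _sim(3)
        for a in build_assays(sim.genome, _truth_loci(sim)):
            chrom_seq = next(
                s for s in sim.genome.values() if a.integrated_left in s
            )
            assert a.integrated_right in chrom_seq

    def test_contig_edge_gives_one_sided_assay(self):
        g = {"c": "ACGTACGTAC" + "G" * 200 + random_dna(np.random.default_rng(0), 100)}

        class L:
            chrom, start, end = "c", 10, 210
            tsd_seq, locus_id = None, "edge"

        a = build_assays(g, [L()], flank_len=60)[0]
        assert a.integrated_left is None and a.empty is None
        assert "one-sided" in a.note

    def test_n_rich_flank_flagged_unreliable(self):
        g = {"c": "N" * 60 + "G" * 200 + "A" * 60}

        class L:
            chrom, start, end = "c", 60, 260
            tsd_seq, locus_id = None, "nn"

        a = build_assays(g, [L()], flank_len=60)[0]
        assert not a.reliable


class TestGenotypeSample:
    def test_carrier_and_noncarrier_states(self):
        sim = _sim(4)
        assays = build_assays(sim.genome, _truth_loci(sim))
        for sample, present_expected in (("polar_1", True), ("black_1", False)):
            hap = pe.haplotype_genome(sim, sample)
            reads = pe.simulate_reads(hap, coverage=30, error_rate=0.005,
                                      seed=11, sample_id=sample)
            calls = genotype_sample(assays, reads, sample_id=sample)
            for c in calls:
                t = next(t for t in sim.truth if t.feature_id == c.locus_id)
                want = "present" if sample in t.present_in else "absent"
                assert c.state == want
                if c.state == "present":
                    assert c.reads_supporting_empty < 2

    def test_no_reads_gives_no_data(self):
        sim = _sim(5)
        assays = build_assays(sim.genome, _truth_loci(sim))
        calls = genotype_sample(assays, [], sample_id="x")
        assert {c.state for c in calls} == {"no_data"}

    def test_mixed_reads_give_both(self):
        sim = _sim(6)
        assays = build_assays(sim.genome, _truth_loci(sim))[:1]
        hap_in = {k: sim.genome[k] for k in sim.genome}
        hap_out = pe.haplotype_genome(sim, "black_1")
        reads = pe.simulate_reads(hap_in, coverage=20, error_rate=0.0, seed=1,
                                  sample_id="het_a") + pe.simulate_reads(
            hap_out, coverage=20, error_rate=0.0, seed=2, sample_id="het_b"
        )
        calls = genotype_sample(assays, reads, sample_id="het")
        assert calls[0].state == "both"

    def test_concordance_over_replicates_with_polymorphism(self):
        """≥99% of (locus, sample) calls match truth at 30x over replicates."""
        ok = tot = 0
        poly_seen = False
        for seed in range(6):
            sim = _sim(40 + seed)
            assays = build_assays(sim.genome, _truth_loci(sim))
            for si, sample in enumerate(("polar_1", "brown_1", "black_1")):
                hap = pe.haplotype_genome(sim, sample)
                reads = pe.simulate_reads(hap, coverage=30, error_rate=0.005,
                                          seed=900 + 10 * seed + si,
                                          sample_id=sample)
                for c in genotype_sample(assays, reads, sample_id=sample):
                    t = next(t for t in sim.truth if t.feature_id == c.locus_id)
                    want = "present" if sample in t.present_in else "absent"
                    tot += 1
                    ok += c.state == want
            present_sets = [t.present_in for t in sim.truth]
            if any(s != present_sets[0] for s in present_sets):
                poly_seen = True
        assert poly_seen  # scenario includes insertion polymorphism
        assert ok / tot >= 0.99


class TestInSilicoPcr:
    FWD = "AGCCTACTTGGGATGACTGC"
    REV = "GAGACCAGCCACTAGAGCCT"

    def test_planted_sites_give_312bp_product(self):
        rng = np.random.default_rng(0)
        tmpl = (
            random_dna(rng, 500)
            + self.FWD
            + random_dna(rng, 272)
            + revcomp(self.REV)
            + random_dna(rng, 400)
        )
        assert in_silico_pcr(tmpl, self.FWD, self.REV) == [312]

    def test_absent_primers_no_product(self):
        rng = np.random.default_rng(1)
        assert in_silico_pcr(random_dna(rng, 3000), self.FWD, self.REV) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr("ACGT" * 100, "ACGTACGT", self.REV)

    def test_multiple_forward_sites_enumerated(self):
        rng = np.random.default_rng(2)
        tmpl = (
            random_dna(rng, 100)
            + self.FWD
            + random_dna(rng, 50)
            + self.FWD
            + random_dna(rng, 80)
            + revcomp(self.REV)
            + random_dna(rng, 100)
        )
        products = in_silico_pcr(tmpl, self.FWD, self.REV)
        assert products == sorted([120, 190])

    def test_matches_naive_enumeration(self):
        """Product lengths equal a naive all-pairs scan on ≤10 kb templates."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            tmpl = random_dna(rng, 2000)
            # plant a random number of sites in random orientations
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, len(tmpl) - 50))
                site = self.FWD if rng.random() < 0.5 else revcomp(self.REV)
                tmpl = tmpl[:pos] + site + tmpl[pos + len(site) :]
            got = in_silico_pcr(tmpl, self.FWD, self.REV, max_product=5000)
            assert got == _naive_pcr(tmpl, self.FWD, self.REV, 5000)


def _naive_pcr(template, fwd, rev, max_product):
    out = []
    for seq in (template, revcomp(template)):
        for i in range(len(seq) - len(fwd) + 1):
            if seq[i : i + len(fwd)] != fwd:
                continue
            probe = revcomp(rev)
            for j in range(len(seq) - len(probe) + 1):
                end = j + len(probe)
                if end > i and seq[j:end] == probe and end - i <= max_product:
                    out.append(end - i)
    return sorted(out)
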