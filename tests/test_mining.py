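"""Seed-and-extend mining and LTR boundary refinement against ground truth."""

import numpy as np
import pytest

import paleoerv as pe
from paleoerv._seq import random_dna, revcomp
from paleoerv.mining import CandidateHit


def _one_provirus_sim(seed, **kw):
    cfg = dict(
        n_proviruses=1,
        n_solo_ltrs=2,
        internal_length=2400,
        provirus_scaffold_len=6000,
        solo_scaffold_len=1800,
        n_empty_scaffolds=1,
        empty_scaffold_len=1500,
        provirus_ages=(1.0,),
        recombinant=False,
    )
    cfg.update(kw)
    return pe.simulate_invasion(pe.SimConfig(seed=seed, **cfg))


class TestFindCandidateLoci:
    def test_planted_provirus_one_merged_hit(self):
        sim = _one_provirus_sim(3)
        t = next(t for t in sim.truth if t.kind == "provirus")
        hits = [
            h
            for h in pe.find_candidate_loci(sim.genome, {"q": sim.ancestor.provirus})
            if h.chrom == t.chrom
        ]
        assert len(hits) == 1
        h = hits[0]
        overlap = min(h.end, t.end) - max(h.start, t.start)
        assert overlap / (t.end - t.start) >= 0.95
        assert h.strand == "+" and h.percent_identity > 95

    def test_random_sequence_yields_no_hits(self):
        rng = np.random.default_rng(0)
        genome = {"r": random_dna(rng, 200_000)}
        query = {"q": random_dna(rng, 3000)}
        assert pe.find_candidate_loci(genome, query, min_identity=80,
                                      min_length=200) == []

    def test_strand_symmetry(self):
        sim = _one_provirus_sim(4)
        t = next(t for t in sim.truth if t.kind == "provirus")
        fwd = {t.chrom: sim.genome[t.chrom]}
        rev = {t.chrom: revcomp(sim.genome[t.chrom])}
        q = {"q": sim.ancestor.provirus}
        hf = [h for h in pe.find_candidate_loci(fwd, q) if h.chrom == t.chrom][0]
        hr = [h for h in pe.find_candidate_loci(rev, q) if h.chrom == t.chrom][0]
        L = len(fwd[t.chrom])
        assert hr.strand == "-" and hf.strand == "+"
        assert (hr.start, hr.end) == (L - hf.end, L - hf.start)

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValueError):
            pe.find_candidate_loci({"c": "ACGTXACGT" * 50}, {"q": "ACGT" * 30})

    def test_small_seed_k_rejected(self):
        with pytest.raises(ValueError):
            pe.find_candidate_loci({"c": "ACGT" * 100}, {"q": "ACGT" * 30}, seed_k=4)


class TestRefineBoundaries:
    def test_provirus_boundaries_near_truth(self):
        sim = _one_provirus_sim(5)
        t = next(t for t in sim.truth if t.kind == "provirus")
        h = [h for h in pe.find_candidate_loci(sim.genome, {"q": sim.ancestor.provirus})
             if h.chrom == t.chrom][0]
        locus = pe.refine_boundaries(sim.genome, h, query_ltr=sim.ancestor.ltr_a)
        assert locus.kind == "provirus"
        assert abs(locus.start - t.start) <= 5 and abs(locus.end - t.end) <= 5
        assert abs(locus.ltr5_interval[1] - t.ltr5_interval[1]) <= 5
        assert abs(locus.ltr3_interval[0] - t.ltr3_interval[0]) <= 5

    def test_solo_ltr_refinement(self):
        sim = _one_provirus_sim(6)
        t = next(t for t in sim.truth if t.kind == "solo_ltr")
        h = [h for h in pe.find_candidate_loci(sim.genome, {"q": sim.ancestor.provirus})
             if h.chrom == t.chrom][0]
        locus = pe.refine_boundaries(sim.genome, h, query_ltr=sim.ancestor.ltr_a)
        assert locus.kind == "solo_ltr"
        assert locus.ltr5_interval == (locus.start, locus.end)
        assert abs(locus.start - t.start) <= 5 and abs(locus.end - t.end) <= 5

    def test_gap_interrupted_provirus_keeps_both_ltrs(self):
        sim = _one_provirus_sim(7)
        t = next(t for t in sim.truth if t.kind == "provirus")
        mid = (t.start + t.end) // 2
        genome = dict(sim.genome)
        g = genome[t.chrom]
        genome[t.chrom] = g[:mid] + "N" * 400 + g[mid + 400 :]
        h = [h for h in pe.find_candidate_loci(genome, {"q": sim.ancestor.provirus})
             if h.chrom == t.chrom][0]
        locus = pe.refine_boundaries(genome, h, query_ltr=sim.ancestor.ltr_a)
        assert locus.kind == "provirus"
        assert locus.gap_intervals  # the N run is recorded

    def test_refinement_idempotent(self):
        sim = _one_provirus_sim(8)
        t = next(t for t in sim.truth if t.kind == "provirus")
        h = [h for h in pe.find_candidate_loci(sim.genome, {"q": sim.ancestor.provirus})
             if h.chrom == t.chrom][0]
        locus = pe.refine_boundaries(sim.genome, h, query_ltr=sim.ancestor.ltr_a)
        rehit = CandidateHit(locus.chrom, locus.start, locus.end, locus.strand,
                             99.0, "q", 100)
        again = pe.refine_boundaries(sim.genome, rehit, query_ltr=sim.ancestor.ltr_a)
        assert (again.start, again.end) == (locus.start, locus.end)
        assert again.ltr5_interval == locus.ltr5_interval
        assert again.ltr3_interval == locus.ltr3_interval

    def test_no_structure_reports_partial(self):
        rng = np.random.default_rng(1)
        genome = {"c": random_dna(rng, 4000)}
        hit = CandidateHit("c", 1000, 1600, "+", 90.0, "q", 50)
        locus = pe.refine_boundaries(genome, hit)
        assert locus.kind == "partial" and locus.notes


class TestClassifyLoci:
    def test_empty(self):
        c = pe.classify_loci([])
        assert (c.proviruses, c.solo_ltrs, c.partial, c.total_ltrs) == (0, 0, 0, 0)

    def test_counting_rule(self):
        prov = pe.ErvLocus("p", "c", 0, 1000, "+", "provirus",
                           ltr5_interval=(0, 100), ltr3_interval=(900, 1000))
        solo = pe.ErvLocus("s", "c", 0, 100, "+", "solo_ltr",
                           ltr5_interval=(0, 100))
        part = pe.ErvLocus("x", "c", 0, 300, "+", "partial",
                           ltr5_interval=(0, 100))
        c = pe.classify_loci([prov, solo, part])
        assert (c.proviruses, c.solo_ltrs, c.partial) == (1, 1, 1)
        assert c.total_ltrs == 2 + 1 + 1

    def test_default_scenario_totals_23(self, default_loci):
        c = pe.classify_loci(default_loci)
        assert (c.proviruses, c.solo_ltrs) == (4, 15)
        assert c.total_ltrs == 23


class TestRecoveryProperty:
    def test_recall_and_boundary_accuracy_over_replicates(self):
        """≥90% of planted loci recovered within 10 bp; no false proviruses."""
        found = total = within = 0
        for seed in range(50):
            sim = _one_provirus_sim(100 + seed)
            hits = pe.find_candidate_loci(sim.genome, {"q": sim.ancestor.provirus})
            loci = [
                pe.refine_boundaries(sim.genome, h, query_ltr=sim.ancestor.ltr_a)
                for h in hits
            ]
            by_chrom = {l.chrom: l for l in loci}
            # empty decoy scaffolds must stay empty
            assert not any(l.chrom.startswith("scaffold_empty") for l in loci)
            for t in sim.truth:
                total += 1
                l = by_chrom.get(t.chrom)
                if l is None:
                    continue
                found += 1
                if abs(l.start - t.start) + abs(l.end - t.end) <= 10:
                    within += 1
                if t.kind == "provirus":
                    assert l.kind == "provirus"
        assert found / total >= 0.9
        assert within / total >= 0.9
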