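import pytest

import paleoerv as pe


@pytest.fixture(scope="session")
def default_sim() -> pe.Simulation:
    """The default study scenario: 4 proviruses + 15 solo LTRs, 23 LTRs."""
    return pe.simulate_invasion(pe.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_loci(default_sim):
    """Mined and refined loci of the default scenario (shared: mining is the
    most expensive stage)."""
    sim = default_sim
    hits = pe.find_candidate_loci(sim.genome, {"erv": sim.ancestor.provirus})
    return [
        pe.refine_boundaries(
            sim.genome, h, query_ltr=sim.ancestor.ltr_a, locus_id=f"locus_{i + 1}"
        )
        for i, h in enumerate(hits)
    ]


@pytest.fixture(scope="session")
def default_ltr_msa(default_sim, default_loci):
    """mafft alignment of all recovered LTR sequences, with the expected
    subgroup label per sequence name."""
    sim = default_sim
    truth = {t.chrom: t for t in sim.truth}
    seqs, want = {}, {}
    for locus in default_loci:
        g = sim.genome[locus.chrom]
        t = truth[locus.chrom]
        if locus.kind == "provirus":
            a, b = locus.ltr5_interval, locus.ltr3_interval
            seqs[f"{locus.locus_id}_LTR5"] = g[a[0] : a[1]]
            seqs[f"{locus.locus_id}_LTR3"] = g[b[0] : b[1]]
            want[f"{locus.locus_id}_LTR5"] = (
                "A" if t.ltr_subgroup in ("A", "recombinant") else "B"
            )
            want[f"{locus.locus_id}_LTR3"] = t.ltr_subgroup
        elif locus.kind == "solo_ltr":
            seqs[f"{locus.locus_id}_solo"] = g[locus.start : locus.end]
            want[f"{locus.locus_id}_solo"] = t.ltr_subgroup
    msa = pe.mafft_align(seqs)
    return msa, want
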