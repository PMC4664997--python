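"""Mine a genome for ERV loci, refine LTR boundaries, and annotate TSD/PBS.

Recovers the planted insertions of the default simulation by seed-and-extend
search with the ancestral provirus as query, then reports how close the
inferred boundaries are to the truth.
"""

from paleoerv import (
    SimConfig,
    classify_loci,
    detect_pbs,
    detect_tsd,
    find_candidate_loci,
    refine_boundaries,
    simulate_invasion,
)

sim = simulate_invasion(SimConfig(seed=1))
hits = find_candidate_loci(sim.genome, {"erv_consensus": sim.ancestor.provirus})
loci = [
    refine_boundaries(sim.genome, h, query_ltr=sim.ancestor.ltr_a,
                      locus_id=f"locus_{i + 1}")
    for i, h in enumerate(hits)
]
counts = classify_loci(loci)
print(f"{counts.proviruses} proviruses, {counts.solo_ltrs} solo LTRs, "
      f"{counts.total_ltrs} LTRs in total\n")

truth = {t.chrom: t for t in sim.truth}
print(f"{'locus':<10}{'kind':<10}{'boundary err (bp)':<19}{'TSD':<8}PBS")
for locus in loci[:6]:
    t = truth[locus.chrom]
    err = abs(locus.start - t.start) + abs(locus.end - t.end)
    tsd = detect_tsd(sim.genome, locus).tsd_seq
    pbs = "-"
    if locus.kind == "provirus":
        seq = sim.genome[locus.chrom][locus.start : locus.end]
        call = detect_pbs(seq, ltr5_end=locus.ltr5_interval[1] - locus.start)
        pbs = f"{call.trna_name} ({call.mismatches} mm)" if call else "none"
    print(f"{locus.locus_id:<10}{locus.kind:<10}{err:<19}{tsd:<8}{pbs}")

# A boundary error of 0 means both outer edges match the planted insertion
# exactly; proviruses should show the tRNA-Pro primer-binding site just
# inside their 5' LTR, as gammaretroviruses do.
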