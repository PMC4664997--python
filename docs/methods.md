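# Methods

This note documents the models, parameter choices and numerical decisions
behind `paleoerv`, and what the simulation-based tests do and do not
demonstrate about real data.

## The simulated invasion

`simulate_invasion` builds an ancestral gammaretrovirus-like element — 500-bp
LTRs with canonical 5′-TG…CA-3′ termini, an internal region of ~6.9 kb
carrying a tRNA-Pro primer-binding site, back-translated *gag*/*pro*/*pol*/
*env* coding regions and a polypurine tract (provirus ≈ 7.9 kb, matching the
scale of a real proviral consensus) — and plants copies into random host
scaffolds, one insertion per scaffold:

* **Integration mechanics.** Each insertion duplicates `tsd_length` (default
  4) bp of host sequence on both sides; truth records keep the TSD,
  coordinates (0-based half-open internally; reports print 1-based
  inclusive), per-LTR intervals and gene coordinates.
* **Post-insertional decay.** Substitutions are applied per site with
  probability *r·T* (rate 0.0015/site/Myr, a published bear genome rate; age
  *T* per insertion), independently on the two LTRs and the internal region,
  with transitions:transversions 2:1 and a 10× multiplier at CpG sites of the
  starting sequence (both positions of the dinucleotide). 10× is a
  conventional mammalian hypermutability factor. The expected LTR-pair
  divergence is therefore 2*rT*, calibrated by test.
* **Default scenario.** 4 proviruses (ages 0.625, 2.1875, 0 and 1.5 Myr; the
  age-0 one is present only in the "polar" samples, mirroring a young,
  lineage-specific insertion) plus 15 solo LTRs, i.e. 23 planted LTRs in two
  subgroups (A/B templates differing at ~2% of sites) with exactly one A/B
  recombinant 3′ LTR (template switch at LTR position 200). Sample
  presence/absence emulates a fixed-in-one-lineage, polymorphic-in-another
  pattern: "brown" samples lack some loci (one provirus deterministically,
  solos at random), the "black" sample carries none of the insertion sites.
* **Reads.** Uniform single-end sampling on both strands at the requested
  coverage, i.i.d. substitution errors, flat Phred qualities.

**What the simulator does not emulate:** indels and microsatellite slippage,
segmental duplication, nested-element insertion, ancient-DNA damage, library
or mapping biases, and full lineage sorting across a species tree (presence
is a per-sample set, not a coalescent realisation). Passing recovery tests
therefore shows correctness of the algorithms under substitution-only decay
on unique sequence — not robustness to repeat-rich real assemblies, where
boundary and TSD errors will be larger.

## Mining and boundary refinement

Candidate loci come from exact k-mer seeding (k=12) with ungapped x-drop
extension (+1/−2, x-drop 20), both strands, hits merged when ≤2 kb apart on
one strand so gap-interrupted proviruses stay one candidate. Refinement
expands a hit by 1 kb and local-aligns the window's two ends against each
other to find the LTR direct repeat (length 300–1200, identity ≥85%); a solo
LTR is found by local alignment against the query LTR. Deliberately harsh
local-alignment scoring (+1/−2, gaps −7/−2) prevents terminal extension into
random flank, which milder retroviral-style scoring allowed in testing.

Outer edges are snapped over a ±10 bp grid to the offset that best shows the
two signatures integration leaves: an exact flanking 4–5 bp duplication
(weight 2 per bp) and TG…CA termini (weight 2 each), ties resolved toward
the smallest shift. Restricting the snap-time TSD to 4–5 bp (detect-time
scanning still reports up to 6) resolves a systematic ambiguity where an
element-terminal `CA` mimics a longer duplication. Two residual,
information-theoretic failure modes remain and are accepted: a TSD inside a
homopolymer makes the boundary genuinely ambiguous under shifts, and a
neighbouring base coincidentally extending the duplication makes the
"longest exact duplication" the correct call even though the planted TSD was
shorter; truth comparisons in the tests treat the latter as a match.

## TSD, PBS, puteins

`detect_tsd` is an exact scan, longest k ∈ [4,6] wins; loci at contig edges
or with N in a flank report "not determinable", mirroring draft-assembly
reality. `detect_pbs` matches the reverse complement of tRNA 3′ 18-mers
within 5 bp of the 5′ LTR end, ranked by mismatches then length (≤2
mismatches). The bundled tRNA library is **synthetic**: representative
18-mers ending in the universal CCA, sufficient for round-trip testing
because the simulator plants its PBS from the same file; for real analyses
supply a genuine tRNA 3′-end FASTA.

`reconstruct_putein` aligns locus DNA to a reference protein with a
semi-global DP (reference fully aligned, free DNA ends) over BLOSUM62. Moves
per cell: 3-nt codon match; 2-nt and 4-nt frameshift codons — a 1-nt
deletion or insertion inside the codon, charged −20 and emitting the best
*repair-compatible* translation (any single-base completion of the 2-mer,
any single-base deletion from the 4-mer); a bare 1-nt insertion (−20); and a
reference gap (−8). In-frame stops emit 'X' at −10. Scoring the repaired
translation (rather than blindly emitting the reference) is what lets a
single mid-codon indel reconstruct the protein exactly while still counting
one frameshift. Frameshift counts are read off the optimal backtrack;
co-optimal paths are disambiguated by a fixed move order, so counts on
heavily decayed input should be read as "a" minimal-cost repair, not "the"
repair. Identity is computed over emitted columns, repaired columns
included. This is a declared simplification of full retroviral annotation
suites (no motif models, no LTR/leader heuristics); per-gene identities on
real decayed loci are not expected to match such tools exactly.

## Consensus and subgroups

`majority_consensus`: per-column plurality over A/C/G/T; columns where gaps
outnumber every base are dropped (default) and base ties become IUPAC codes.
`assign_subgroups` clusters sequences into two groups and flags mosaics:

1. pairwise K2P distances (p-distance fallback at saturation);
2. initial 2-way split on the sign of the first principal coordinate
   (classical MDS). An average-linkage 2-cut was tried first and discarded:
   its top split isolates a single noisy sequence whenever one sequence
   carries ~2× the expected noise, which happens routinely at 23×500 bp;
   the first PCoA axis is dominated by the group signal instead. Linkage
   remains as fallback for degenerate axes;
3. k-medoids-style polish: reassign each sequence to the nearer group
   consensus until stable;
4. diagnostic columns: ≥50% coverage, group consensuses differ, ≥80%
   within-group agreement; a sequence matching one group's alleles over one
   span and the other's over a disjoint span (≥3 own-group sites per side,
   ≥80% side purity, and better than any single-group explanation) is
   labelled recombinant and removed; diagnostics are then recomputed once.
   The larger group is called A (ties: lexicographically smallest member),
   making labels invariant to input order.

With ~10 diagnostic sites per 500 bp (2% template divergence), a recombinant
whose shorter segment contains <3 diagnostic sites is undetectable by
construction; the acceptance threshold (≥22/23 correct labels) budgets for
exactly this case.

## Recombination scan

`savings_scan` computes cost0 (best single source, mismatch=1, gap-vs-base=1,
N free) and costR (min-cost source path with switches charged α=1) by DP;
savings = cost0 − costR ≥ 0. The reported interval runs from one past the
last column *supporting* the left source (target matches it and not the
right source) to the first column supporting the right source — a convention
that yields both single-column reports and ~30-column intervals depending on
diagnostic density; with multiple switches the one with the largest local
gain is reported. The permutation p-value shuffles column order jointly
(1000 permutations, batched DP), so p_min = 1/1001 with the add-one
correction; column sums are permutation-invariant, hence cost0 need not be
recomputed. Type-I error is controlled by construction (the null "no column
order structure" is exactly what permutation destroys) and verified at ≤7%
nominal 5% over 200 replicates. `sliding_window_scan` reports the nearest
reference per window by p-distance, keeping the previous reference on ties
so only genuine switches mark breakpoints.

## Dating

`k2p_distance` drops gap/N columns and, with `exclude_cpg` (default), every
column where **either** sequence participates in a CpG dinucleotide — the
symmetric rule, chosen because a hypermutated CpG is typically visible in
only one of the two copies. Consequence, measured in the recovery tests: a
substitution that *creates* a CpG is also excluded, removing ~15% of true
clock signal and biasing ages downward by a similar fraction (the default
scenario's 2-Myr provirus dates to ~1.75 Myr in expectation). This is a
property of CpG-excluded LTR dating generally, not of this implementation;
the acceptance band (|mean error| ≤ 0.3 Myr) absorbs it.

`date_provirus` computes T = D/(2r) and a percentile bootstrap CI (1000
category resamples of the used columns). A pair with zero observed
differences has a degenerate bootstrap, so its upper bound is the exact
binomial (Clopper–Pearson) upper limit for 0 successes in n sites mapped
through T = D/(2r), and the estimate is flagged "young — clock
uninformative"; without this the nominal 95% interval would cover a true age
of 0.5 Myr less than 55% of the time (P(no substitutions) ≈ 0.47 at 500 bp).
Saturated distances (log arguments ≤0) raise rather than return; pairs
flagged recombinant are refused (reported ND), since a mosaic LTR violates
the identical-at-integration premise. Reports round D to 3 decimals and T to
4; internal arithmetic is unrounded.

## Genotyping

`build_assays` derives three probes per locus from the reference: integrated
5′ junction (60 bp flank + LTR head), integrated 3′ junction, and the empty
site — left flank (which already ends in the single retained TSD copy)
joined directly to the post-TSD right flank. Contig-edge loci get one-sided
assays; flanks >20% N mark the assay unreliable. `genotype_sample` calls a
read supporting an allele when it covers a junction-centred 40-mer
(2×20 bp overhang) with ≤1 mismatch, seeded by exact 20-mer halves for
speed; ≥2 supporting reads per allele give present/absent/both, otherwise
no_data. This exact-probe matcher replaces read mapping deliberately: it is
exact on substitution-only synthetic reads and transparent to test, but it
does not handle indels near junctions or mapping-quality issues that a real
aligner would. `in_silico_pcr` enumerates primer pairings on both strands
(products inclusive of primers, ≤2 kb by default).

## Problem sizes used in tests

Simulation-backed checks run at desk scale chosen to keep the statistical
targets meaningful: the default 23-LTR scenario (~100 kb genome) for mining/
subgroup/genotyping acceptance; 100 replicates per age point for dating
recovery; 20 mosaic replicates and 200 null replicates for the savings scan;
exhaustive path enumeration up to 12 columns × 4 sources. Property tests use
reduced single-provirus scenarios (~12 kb) over 50 seeds.

## Known limitations

* Boundary refinement assumes largely co-linear, substitution-decayed LTRs;
  heavily deleted or nested elements fall back to `partial`.
* The savings DP reports one breakpoint interval even when ≥2 switches are
  optimal (the highest-gain one), matching single-interval report tables.
* Subgroup assignment assumes exactly two groups; more-structured families
  will be forced into the nearest 2-partition.
* Dating CIs are per-locus and do not propagate rate uncertainty; halving
  the rate doubles every age.
* `simulate_reads` has no quality trajectory or adapter artefacts; FASTQ
  parsing of malformed records is skip-with-warning, not repair.
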