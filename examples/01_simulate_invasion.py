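"""Simulate a retroviral germline invasion with known ground truth.

Builds the default scenario — 4 proviruses and 15 solo LTRs (23 LTRs in
total, one of them an A/B recombinant) planted in random host scaffolds —
and prints what was planted where.
"""

from paleoerv import SimConfig, simulate_invasion

sim = simulate_invasion(SimConfig(seed=1))

print(f"{len(sim.genome)} scaffolds, {len(sim.truth)} planted features\n")
print(f"{'feature':<14}{'kind':<10}{'subgroup':<12}{'age (Myr)':<11}TSD")
for t in sim.truth:
    print(f"{t.feature_id:<14}{t.kind:<10}{t.ltr_subgroup:<12}"
          f"{t.true_age_myr:<11.3f}{t.tsd_seq}")

# Each row is one planted insertion: proviruses carry two LTRs whose
# divergence clocks the listed age; the TSD is the 4-bp host duplication
# created at integration and used later for boundary and junction checks.
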