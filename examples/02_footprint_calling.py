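"""Footprint calling from simulated footprint-library site tables.

Simulates two tumors whose genomes carry true excision footprints,
endogenous TACWGTA loci (shared with a matched normal), and surviving
insertions; runs the sequential filters; tiers the survivors by depth;
and scales by validation rates to estimate true footprint numbers.
"""

from sbkit import footprints, simulate as sim
from sbkit.genome import ReferenceGenome

# genome with engineered TA sites for footprints and insertions
base = sim.random_genome({"chr1": 30_000}, seed=1)
seq = list(base["chr1"])
for p in range(1_000, 9_001, 1_000):
    seq[p : p + 2] = "TA"
genome = ReferenceGenome({"chr1": "".join(seq)})

footprint_sites = {
    "tumorA": [("chr1", 1_000), ("chr1", 2_000), ("chr1", 3_000)],
    "tumorB": [("chr1", 4_000), ("chr1", 5_000)],
}
insertion_sites = {"tumorA": [("chr1", 6_000)], "tumorB": [("chr1", 7_000)]}

tables, truth = sim.simulate_footprint_library(
    genome, footprint_sites, insertion_sites, depth=400, seed=2
)
n_endo = len(truth[(truth["sample"] == "normal")])
print(f"endogenous TACWGTA loci in the genome: {n_endo}")

calls = footprints.call_candidates(
    {s: tables[s] for s in ("tumorA", "tumorB")},
    tables["normal"],
    clonal_insertions=insertion_sites,
)
for sample, cands in calls.items():
    print(f"{sample}: {len(cands)} candidates after filtering "
          f"(truth: {len(footprint_sites[sample])} real footprints)")

# tier by depth against clonal reference loci, then estimate
validation = [
    footprints.ValidationRecord("high", 12, 12),
    footprints.ValidationRecord("low", 18, 1),
]
for sample, cands in calls.items():
    tiered = footprints.assign_confidence(cands, clonal_site_depths=[300, 400, 500])
    n_high = sum(c.confidence == "high" for c in tiered)
    n_low = len(tiered) - n_high
    est = footprints.estimate_true_footprints(n_high, n_low, validation)
    print(f"{sample}: {n_high} high / {n_low} low confidence -> "
          f"estimated {est} bona fide footprints")
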