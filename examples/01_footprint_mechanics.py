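"""Transposon integration and excision mechanics at a TA dinucleotide.

Builds a tiny sequence, integrates a transposon (duplicating the TA
target site), excises it again, and shows the 5-bp footprint left at
the donor locus.
"""

from sbkit.genome import FOOTPRINT_VARIANTS, ReferenceGenome, scan_motif
from sbkit.simulate import apply_excision, apply_insertion

locus = "GGCATTAGCATCG"  # TA at position 5
transposon = "CAGTTGAAGTCGG"

print(f"donor locus        : {locus}")
inserted = apply_insertion(locus, 5, transposon)
print(f"after integration  : {inserted}  (+{len(inserted) - len(locus)} bp, TA duplicated)")
for variant in FOOTPRINT_VARIANTS:
    excised = apply_excision(inserted, 5, transposon, variant)
    hits = scan_motif(ReferenceGenome({"c": excised}), "TACWGTA", both_strands=False)
    print(
        f"after excision     : {excised}  "
        f"(+{len(excised) - len(locus)} bp vs original; {variant} footprint "
        f"found by scanner at {hits[0].start})"
    )

# The +5 bp is what makes a footprint inside a coding exon a
# frameshift mutation: 5 is not a multiple of 3.
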