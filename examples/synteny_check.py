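"""Check the conserved rpmH-rnpA-yidD arrangement in two annotations.

In many bacteria rnpA (the RNase P protein gene) sits immediately between
rpmH and yidD on one strand.  A genome where no RNase P RNA is called can be
screened for this context: if the whole arrangement is missing too (as in
the reduced genomes of sap-sucking-insect endosymbionts), gene loss is the
more likely explanation than a missed call.
"""

from rnpbscan import GeneFeature, check_rnpa_context

print("typical bacterial genome:")
genes = [
    GeneFeature("rpmH", 100, 300, "plus"),
    GeneFeature("rnpA", 350, 700, "plus"),
    GeneFeature("yidD", 750, 1000, "plus"),
    GeneFeature("dnaA", 2000, 3500, "plus"),
]
result = check_rnpa_context(genes)
print(f"  present: {result.present}")
print(f"  arrangement found: {result.arrangement_found}")

print("\nreduced endosymbiont-like genome (arrangement deleted):")
endo = [GeneFeature("trpA", 10, 900, "plus"), GeneFeature("ilvD", 1000, 2500, "plus")]
result = check_rnpa_context(endo)
print(f"  present: {result.present}")
print(f"  arrangement found: {result.arrangement_found}")
print(f"  violations: {result.violations}")

print("\ngenome with an extra gene wedged between rpmH and rnpA:")
wedged = genes + [GeneFeature("mysteryORF", 310, 340, "plus")]
result = check_rnpa_context(wedged)
print(f"  arrangement found: {result.arrangement_found}")
print(f"  violations: {result.violations}")
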