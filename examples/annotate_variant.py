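"""Annotate a single novel missense variant against a paralogue family.

Loads the packaged ryanodine-receptor family (RYR2 query; RYR1/RYR3
paralogues) and asks whether the CPVT-cohort variant RYR2 p.G357S lands on
a residue whose equivalent position in a paralogue carries a known
disease-causing variant.
"""

from paranno import annotate_query_variant, load_paper_fixture, parse_protein_hgvs

fixture = load_paper_fixture("RYR")
variant = parse_protein_hgvs("p.G357S", "RYR2")

annotations = annotate_query_variant(variant, fixture.bundle)
print(f"query: {variant}")
for a in annotations:
    print(
        f"  {a.paralogue_gene} {a.paralogue_variant.hgvs} ({a.disease}), "
        f"consensus {a.consensus}, conserved={a.conserved}, tier {a.tier.name}"
    )
# One line per paralogue disease variant at the equivalent residue.  RYR1
# G341R causes malignant hyperthermia; the glycine is conserved between the
# proteins and the alignment consensus is 9/9, so the transfer is HIGH
# quality — strong evidence that RYR2 residue 357 is intolerant of variation.
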