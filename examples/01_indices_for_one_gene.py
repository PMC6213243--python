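"""Compute the full index panel for a single coding sequence.

Builds a short CDS by hand, then prints its positional GC contents, RSCU
values for one family, ENc, and the protein-level Gravy/Aromo scores.
A CAI needs a reference gene: here the gene is scored against itself, which
by construction gives the maximal value 1.0.
"""

from cubkit import (
    CdsRecord,
    cai,
    cai_reference,
    count_codons,
    enc,
    gravy,
    aromo,
    positional_gc,
    rscu,
    translate,
)

# a repeating unit populating 2-, 3-, 4- and 6-fold families: the two-fold
# families are used evenly, the larger families use only two of their codons
unit = "GATGACTTTTTCGCTGCACTTTTAATTATC"  # D D F F A A L L I I
cds = CdsRecord("demo", "ATG" + unit * 12 + "TGGTAA")

counts = count_codons(cds)
pos = positional_gc(counts)
table = rscu(counts)
protein = translate(cds).protein
ref = cai_reference(counts)

print(f"gene {cds.gene_id}: {cds.length_nt} nt, {cds.length_aa} aa")
print(f"GC_cds={pos.gc_cds:.3f}  P1={pos.p1:.3f}  P2={pos.p2:.3f}  "
      f"P12={pos.p12:.3f}  P3={pos.p3:.3f}")
print(f"RSCU Asp: GAU={table['GAU']:.2f}  GAC={table['GAC']:.2f}  "
      f"(even usage: no bias)")
print(f"RSCU Leu: CUU={table['CUU']:.2f}  UUA={table['UUA']:.2f}  "
      f"CUC={table['CUC']:.2f}  (six-fold family, two codons carry all use)")
print(f"ENc={enc(counts):.2f}  (20 = extreme bias, 61 = even usage)")
print(f"CAI vs itself={cai(counts, ref):.2f}  (self-reference is maximal)")
print(f"Gravy={gravy(protein):.3f}  Aromo={aromo(protein):.3f}")
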