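"""Peptide mass and fragment-ion arithmetic for a phosphopeptide.

Uses the EGFR tryptic peptide GSHQISLDNPDYQQDFFPK (protein residues
1161-1179); phosphorylation at peptide position 6 corresponds to the
autophosphorylation-adjacent site S1166.
"""

from phosphodia import fragment_ladder, parse_modified_sequence, peptide_mono_mass, precursor_mz

plain = parse_modified_sequence("GSHQISLDNPDYQQDFFPK")
phos = parse_modified_sequence("GSHQIS(ph)LDNPDYQQDFFPK")

print(f"unmodified mass : {peptide_mono_mass(plain):.5f} Da")
print(f"phospho mass    : {peptide_mono_mass(phos):.5f} Da")
print(f"delta           : {peptide_mono_mass(phos) - peptide_mono_mass(plain):.5f} Da  (one phosphate)")
print(f"precursor m/z 2+: {precursor_mz(phos, 2):.5f} Th")

ions = fragment_ladder(phos, include_neutral_loss=True)
b5 = next(f for f in ions if f.name == "b5^1")
b6 = next(f for f in ions if f.name == "b6^1")
b6_loss = next(f for f in ions if f.name == "b6-H3PO4^1")
print(f"\nb5 (no phospho in fragment)  : {b5.mz:.4f} Th")
print(f"b6 (carries the phosphate)   : {b6.mz:.4f} Th")
print(f"b6 - H3PO4 neutral loss      : {b6_loss.mz:.4f} Th")
print("\nThe +79.966 Da jump between b5 and b6 places the phosphate on S6;")
print("the -97.977 Da variant is the phosphate neutral loss used in libraries.")
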