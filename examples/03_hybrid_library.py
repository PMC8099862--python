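"""Hybrid spectral-library assembly: fragment filtering, merge, iRT fit.

Builds small DDA and DIA archives for two phosphopeptides, applies the
fragment quality rules (m/z 300-1800, >= 5% relative intensity, >= 3
residues, top 15), merges them into a hybrid library, and calibrates
measured retention time against iRT.
"""

import numpy as np

from phosphodia import filter_fragments, fit_irt_calibration, library_summary, merge_hybrid
from phosphodia.library import LibraryEntry, LibraryFragment
from phosphodia.masscalc import parse_modified_sequence, precursor_mz


def entry(mseq, source, score, irt):
    pf = parse_modified_sequence(mseq)
    n = len(pf.stripped_sequence)
    frags = tuple(
        LibraryFragment("y", i, 1, 250.0 + 110.0 * i, 1.0 / i, i)
        for i in range(1, n)
    )
    return LibraryEntry(pf, precursor_mz(pf, 2), 2, irt, frags, source, score, ("P00533",))


dda = [entry("GS(ph)HQISLDNPDYQQDFFPK", "DDA", 1.2, 55.0), entry("AS(ph)DEFGHK", "DDA", 0.9, 20.0)]
dia = [entry("AS(ph)DEFGHK", "DIA", 1.7, 20.5), entry("TT(ph)PDEYQRK", "DIA", 1.1, 70.0)]

lib = merge_hybrid(dda, dia)
lib.entries = {k: filter_fragments(e) for k, e in lib.entries.items()}
print("provenance:", lib.provenance_counts, "(shared precursors keep the best spectrum)")
for key, e in lib.entries.items():
    print(f"  {key[0]} {key[1]}+: {len(e.fragments)} fragments kept, source={e.source}")

summary = library_summary(lib)
print(f"\nsummary: {summary['n_precursors']} precursors, "
      f"pS/pT fractions {summary['pS_fraction']:.2f}/{summary['pT_fraction']:.2f}")

rng = np.random.default_rng(0)
irt = np.linspace(0, 100, 30)
rt = 0.9 * irt + 12.0 + rng.normal(0, 0.2, irt.size)
cal = fit_irt_calibration(list(zip(irt, rt)))
print(f"\niRT calibration: RT = {cal.slopes[0]:.3f} * iRT + {cal.intercepts[0]:.2f}, "
      f"R^2 = {cal.r_squared:.4f}")
print(f"predicted RT at iRT 50: {cal.predict(50.0):.2f} min")
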