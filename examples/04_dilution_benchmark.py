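"""The spike-in dilution benchmark end to end.

Generates a 166-phosphopeptide panel (139 mono-, 21 di-, 6 tri-phospho) from
61 synthetic proteins, simulates the five-level dilution series (2, 1, 0.5,
0.2, 0.1 units, triplicate) with 5% multiplicative noise, rolls precursor
areas up to phosphosites, and reports linearity, ratio accuracy, and CV.
"""

from phosphodia import DilutionDesign, cv_profile, dilution_linearity, ratio_accuracy, rollup_phosphosites
from phosphodia import io as pio
from phosphodia.simulate import make_fasta, make_panel, simulate_dilution_report

SEED = 1
fasta = make_fasta(61, seed=SEED)
proteins = pio.read_fasta_text(fasta)
panel = make_panel(fasta, seed=SEED)
mono = sum(1 for e in panel if e.n_phospho == 1)
print(f"panel: {len(panel)} phosphopeptides ({mono} mono-phospho)")

design = DilutionDesign()
records, truth = simulate_dilution_report(panel, design, noise_cv=0.05, seed=SEED)
matrix = rollup_phosphosites(records, proteins, mode="libDIA")
print(f"site matrix: {len(matrix.sites)} phosphosites x {len(matrix.runs)} runs")

ratios = ratio_accuracy(matrix, design)
print("\nmeasured vs expected fold ratios (median over sites):")
print(ratios[["expected_ratio", "median_ratio", "n_sites"]].to_string(
    float_format=lambda v: f"{v:.3f}"))

lin = dilution_linearity(matrix, design)
print(f"\nmedian linearity R^2 across sites: {lin['r_squared'].median():.4f}")

cv, median_cv = cv_profile(matrix, design.run_ids("L2"))
print(f"median CV% among triplicates at the top level: {median_cv:.2f}%")
print("\nWith 5% simulated noise the median per-site CV sits near 4-5% and the")
print("median ratios track the designed 1/2/4/10/20-fold dilution almost exactly.")
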