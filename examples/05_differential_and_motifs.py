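"""Differential phosphosite testing and kinase-motif enrichment.

Simulates a 3-vs-3 comparison of 1000 sites (log2 scale) with 50 sites
shifted by 2 log2 units, runs the S0-moderated permutation-FDR test, and
then demonstrates Fisher motif enrichment on 13-mer windows.
"""

from phosphodia import extract_motif_windows, fisher_motif_enrichment, permutation_fdr
from phosphodia.simulate import simulate_two_group_matrix
from phosphodia.stats import DEFAULT_MOTIFS

matrix, truth = simulate_two_group_matrix(
    n_sites=1000, n_per_group=3, n_changed=50, effect_log2=2.0, sd=0.25, seed=11
)
result = permutation_fdr(matrix, truth["labels"], s0=0.1, fdr_threshold=0.01, seed=11)
sig = set(result.significant_sites)
planted = set(truth["changed_sites"])
print(f"{result.n_permutations} label permutations; "
      f"{len(sig)} sites significant at FDR < 0.01")
print(f"recovered {len(sig & planted)}/{len(planted)} planted effects, "
      f"{len(sig - planted)} false positives")

# motif enrichment: proline-directed foreground against a mixed background
fg = ["AAAAAASPAAAAA"] * 30 + ["AAAAAASAAAAAA"] * 10
bg = ["AAAAAASPAAAAA"] * 40 + ["AAAAAASAAAAAA"] * 360
table = fisher_motif_enrichment(fg, bg, patterns=DEFAULT_MOTIFS, fdr_threshold=0.02)
enriched = table[table["enriched"]]
print("\nenriched motifs (Fisher exact, BH FDR < 0.02):")
print(enriched[["fg_match", "bg_match", "odds_ratio", "q_value"]].to_string(
    float_format=lambda v: f"{v:.3g}"))
print("\nThe proline-directed class (pS/pT-P, the ERK/CDK signature) stands out")
print("because +1 proline is 7.5x more frequent in the foreground windows.")
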