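# phosphodia

A desk-scale toolkit for quantitative DIA phosphoproteomics: phosphosite
localization from fragment-ion evidence, hybrid DDA+DIA spectral-library
assembly, precursor-to-phosphosite abundance roll-up, spike-in dilution
benchmarking, and permutation-FDR differential testing — driven by
synthetic-data generators that emulate a 166-phosphopeptide spike-in
benchmark, so every capability can be exercised and validated without
instrument data.

## Who it is for

Computational proteomics developers and analysts who want a transparent,
testable reference implementation of the site-centric DIA quantification
workflow: the logic that sits *downstream* of signal extraction (peak-area
reports) and *upstream* of biological interpretation.  Raw-spectrum
deconvolution, peptide-spectrum scoring, and search-engine FDR are out of
scope: the package consumes precursor-level quantification reports and
spectral-library tables.

## The methods at its core

**Site localization.** Positional isomers of a phosphopeptide (same
sequence, k phosphates on different S/T/Y residues) are distinguished by
*site-determining ions* — b/y fragments whose m/z differs between isomers.
Each configuration c is scored Ascore-style against the observed peak list:
after keeping the top-*d* peaks per 100 Th (default d = 10), with k of n
theoretical singly charged b/y ions matched within ±0.05 Da,

    score(c) = −10·log10 P(X ≥ k),   X ~ Binomial(n, p),   p = d·(2·tol)/100.

Configuration weights 10^(score/10) are normalized to probabilities and
marginalized per site; a site is **class 1** when its probability is ≥ 0.75
(DDA / library-based DIA) or ≥ 0.99 (library-free DIA).

**Site roll-up.** The abundance of a phosphosite (keyed `ACC-S1166` style in
protein coordinates) in a run is the *sum* of the precursor areas of all
peptidoforms containing that site at or above the class-1 cutoff; protein
abundance is the sum over stripped peptide sequences of the *mean* precursor
area.  Missing is missing (NaN), never zero.

**Differential testing.** On log2 abundances, the SAM-style statistic

    d = (x̄_A − x̄_B) / (s_pooled·√(1/n_A + 1/n_B) + S0),   S0 = 0.1 by default,

with a permutation FDR: null |d| pooled over group-label permutations
(observed labeling and its mirror excluded), q = (mean null exceedances per
permutation)/(observed exceedances), monotonized; significant at q < 0.01.
Motif analysis extracts 13-mer windows centered on each site and tests
position-specific kinase-motif patterns by one-sided Fisher's exact test
with Benjamini–Hochberg control at FDR < 0.02.

## Worked example

`examples/04_dilution_benchmark.py` runs the spike-in benchmark end to end:
a 166-phosphopeptide panel (139 mono-, 21 di-, 6 tri-phospho) drawn from 61
synthetic proteins, diluted over five levels (2, 1, 0.5, 0.2, 0.1 units) in
triplicate with 5% multiplicative noise, rolled up to phosphosites:

```
panel: 166 phosphopeptides (139 mono-phospho)
site matrix: 199 phosphosites x 15 runs

measured vs expected fold ratios (median over sites):
       expected_ratio  median_ratio  n_sites
L2              1.000         1.000      199
L1              2.000         1.992      199
L0.5            4.000         4.020      199
L0.2           10.000         9.971      199
L0.1           20.000        20.024      199

median linearity R^2 across sites: 0.9997
median CV% among triplicates at the top level: 4.53%
```

The median measured ratios track the designed 1/2/4/10/20-fold series to
within 1%, per-site regressions of abundance on spike amount are essentially
perfectly linear, and the per-site CV recovers the simulated 5% noise level
(the n = 3 sample CV estimator is slightly biased low).  The other examples
cover fragment arithmetic, spectrum localization, hybrid-library assembly
with iRT calibration, and differential testing with motif enrichment; each
prints what it computes and what the numbers mean.

A thin CLI mirrors the pipeline stages
(`phosphodia simulate | build-library | localize | quant-sites | benchmark |
diffexp | motif`); stochastic commands require `--seed`.

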