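# Methods

This note documents the models, parameter choices, and numerical decisions
behind phosphodia, and what the synthetic benchmark does and does not show
about real data.

## Mass and fragment arithmetic

Monoisotopic residue masses are hard-coded from the standard IUPAC table at
5-decimal precision; water is 18.01056 Da and the proton 1.007276 Da.
Variable-modification deltas are phospho +79.96633 (S/T/Y only), oxidation
+15.99491, carbamidomethyl +57.02146, and acetyl +42.01057 Da.  b ions carry
the N-terminal residue sum, y ions the C-terminal sum plus water; a fragment
inherits every modification inside its residue span.  The only neutral loss
modeled is H3PO4 (−97.9769 Da) on phospho-containing fragments — water and
ammonia losses add match candidates without adding site information, and the
site evidence in this workflow rests on plain b/y (+phospho) ions.  Fragment
charge defaults to 1 and is configurable; a/c/x/z series and isotope
envelopes are out of scope.  The complementarity identity used in tests is
neutral(b_i) + neutral(y_(n−i)) = peptide monoisotopic mass, with neutral
mass defined as z·(m/z − proton).

Modified sequences use an inline parenthesized dialect
(`GS(ph)HQISLDNPDYQQDFFPK`, optional flanking underscores) as the single
canonical internal form; the report reader accepts a header-mapping schema
so other dialects can be adapted at the column level.

## Localization model

The integrated localization scores shipped by commercial DIA software are
unpublished, so phosphodia uses the transparent cumulative-binomial (Ascore
family) model: peaks are reduced to the top *d* = 10 per 100 Th window;
each isomer configuration's singly charged b/y ladder is matched at ±0.05 Da
(the fragment tolerance used throughout); the chance-match probability is
p = d·2·tol/100 (= 0.01 at defaults); and the configuration score is
−10·log10 of the binomial tail P(X ≥ k | n, p), computed via `binom.logsf`
so perfect matches of long ladders do not underflow.  Whole configurations
are scored — never sites independently — and per-site probabilities are
marginals of the normalized 10^(score/10) configuration weights, so they
always sum to the phospho count k.  Ties give equal weights.  Neutral-loss
ions are excluded from the match count by default to keep n well defined
(optional flag).

Because this scorer is a stand-in for proprietary tools, its *absolute*
probabilities will not numerically match theirs; the class-1 cutoffs
(≥ 0.75 for DDA and library-based DIA, ≥ 0.99 for library-free DIA, both
inclusive) are applied to whatever scorer produced the probabilities.

## Library assembly

Fragment quality rules: m/z within 300–1800, relative intensity ≥ 5%,
≥ 3 residues, at most the 15 most intense fragments (intensity ties broken
by ascending m/z), neutral-loss fragments retained.  Survivor intensities
are rescaled to max = 1, which makes the filter idempotent.  PSM quality
thresholds are score ≥ 40, delta score ≥ 8, intensity ≥ 100, length ≥ 7,
all inclusive; upstream 1% search FDR is accepted as a given of the input,
not recomputed.  DDA and DIA archives merge on (modified sequence, charge);
a duplicate key keeps the single higher-scoring spectrum (no consensus
building) and is marked `both`.  Retention-time calibration is segmented
least squares of measured RT on iRT: one segment (ordinary least squares)
by default, since the proprietary "precision iRT" function is not
documented; with n segments, knots sit at iRT quantiles and each segment
needs ≥ 3 points.

## Roll-up and normalization

Site keys are protein-coordinate identifiers (`P00533-S1166`); peptide
position p at peptide offset o maps to protein position o + p − 1, both
1-based.  Peptides occurring more than once in a protein key against the
first occurrence and carry a multi-mapping flag; shared peptides key against
the first accession of the protein-group string (group preserved as
metadata), avoiding double counting.  A multi-phospho precursor contributes
its full area to *every* constituent site at or above the cutoff — site
abundances are deliberately not additive across sites, but are exactly
conservative for mono-phospho input (a tested invariant).  Records without
an explicit probability (single-candidate peptides) count as probability
1.0.  Cross-run normalization is global median-centering in log2 space on
rows complete in all runs; RT-local normalization is not reconstructable
from report-level data and is not attempted.

## Benchmark metrics

CV% is 100·sd/mean on raw abundances with the n−1 denominator (geometric
CV available behind a flag).  Linearity regresses mean abundance per level
on spike amount, with intercept, on linear axes (log-log optional); R² is
the squared Pearson correlation.  Ratio accuracy averages replicate
abundances per level first, then forms reference/level ratios per site and
reports medians per level; the reference is the *highest* spike amount, so
the default (2, 1, 0.5, 0.2, 0.1)-unit design expects ratios 1, 2, 4, 10, 20.
Missing-value profiles rank sites by mean observed abundance (fully missing
sites rank lowest), split them into near-equal tertiles G1 (lowest) to G3,
and report the all/some/one/none completeness partition plus missing-cell
percentages per group.

## Differential statistics

The moderated statistic adds the fudge factor S0 (default 0.1) to the
pooled-t denominator, damping low-variance small effects; at S0 = 0 it
equals the classical pooled t (tested to 1e−12).  The permutation null
enumerates all distinct group-label assignments when there are at most 250
(e.g. all 20 for 3 vs 3), otherwise samples that many without replacement
from a mandatory seed.  The observed labeling and its label-swap mirror are
excluded from the null pool: they reproduce the observed statistics exactly
and would floor the attainable q at 2/(number of assignments), destroying
power at stringent FDR for small designs.  q-values are SAM-style (mean
per-permutation null exceedances over observed exceedances), clipped to
[0, 1] and monotonized along decreasing |d|; testing is complete-case per
site.  Benjamini–Hochberg is available for motif enrichment, which uses a
one-sided Fisher's exact test of position-specific patterns on 13-mer
windows (center = phosphosite, `_`-padded at protein termini) against a
user-supplied background — the documented choice is all quantified sites —
at FDR < 0.02.  The shipped motif table is a small editable set of canonical
kinase classes (basophilic, proline-directed, acidophilic, and pTyr
examples), not an exhaustive motif database.

## Synthetic-data generators

The generators define the study conditions used by the tests and the
acceptance script:

- **Proteins**: 61 random sequences of 150–400 residues, uniform residue
  frequencies, ≥ 1 S/T/Y guaranteed, UniProt-style `sp|SIMi|SIMi_TEST`
  headers.
- **Panel**: tryptic-like peptides (cleave after K/R, no proline rule, no
  missed cleavages), length 7–25, with multiplicity counts (139, 21, 6) for
  mono/di/tri-phosphopeptides — the composition of the emulated
  166-peptide benchmark; true configurations drawn uniformly over the
  candidate S/T/Y combinations.
- **Dilution series**: five levels at 2, 1, 0.5, 0.2, 0.1 units in
  triplicate.  Base abundances are lognormal (10^N(5, 0.5), arbitrary area
  units); per-observation noise is exp(N(0, σ)) with σ = √ln(1 + CV²) so the
  multiplicative CV equals the nominal 5%; dropout, when enabled, is a
  logistic detection curve in log10 abundance with configurable midpoint and
  steepness, which concentrates missingness in the lowest dilution when the
  midpoint sits above that level's typical abundance.
- **Spectra**: the true configuration's singly charged b/y ladder sampled at
  a coverage fraction, lognormal intensities, optional uniform noise peaks;
  ions that discriminate the true isomer from any competitor are flagged in
  the ground truth.
- **Two-group matrices**: log2 values N(baseline, sd) with baseline spread
  1.0 between sites, within-group sd 0.25, and a planted +2.0 log2 shift on
  the changed sites — an 8-fold change at low noise, representing a clearly
  regulated phosphosite.

Every generator is a pure function of (parameters, seed) and serializes its
ground truth, so expected metrics are recomputable without re-simulation.

**What passing these tests does not show.**  The simulations contain no
chromatographic peak shapes, co-fragmentation or interference, no intensity
calibration to any instrument, no correlated (peptide-specific) noise, and
idealized localization evidence.  Real-data figures of merit — absolute CV
levels, identification counts, library sizes — depend on instrument data
and are outside what the synthetic benchmark can certify; what it does
certify is the correctness of the arithmetic, the aggregation contracts,
and the error control of the statistics under the stated models.

## Problem sizes and runtime

Default validation sizes were chosen so the whole suite runs comfortably on
a laptop: 200 random peptide pairs for the site-determining-ion oracle
check, 500 spectra for localization recovery, the full 166-peptide panel
for roll-up and benchmark metrics, and 20 replicate null datasets of 1000
sites (3 vs 3) plus one 1000-site power dataset with 100 planted effects
for the permutation test.  The acceptance script completes in seconds.
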