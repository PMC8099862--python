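"""S0-moderated testing, permutation FDR, protein normalization, and motifs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phosphodia.simulate import simulate_two_group_matrix
from phosphodia.stats import (
    DEFAULT_MOTIFS,
    MotifPattern,
    extract_motif_windows,
    fisher_motif_enrichment,
    normalize_site_to_protein,
    permutation_fdr,
    s0_ttest,
)


class TestS0Ttest:
    def test_hand_computed_example(self):
        # (1+2+3)/3 - (4+5+6)/3 = -3; pooled sd 1, sqrt(2/3) = 0.8165
        d = s0_ttest([1, 2, 3], [4, 5, 6], s0=0.1)
        assert d == pytest.approx(-3 / (math.sqrt(2 / 3) + 0.1), abs=1e-9)
        assert d == pytest.approx(-3.273, abs=1e-3)

    def test_identical_groups_zero(self):
        assert s0_ttest([2.0, 3.0, 4.0], [2.0, 3.0, 4.0], s0=0.1) == 0.0

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_s0_zero_matches_pooled_t(self, data):
        floats = st.floats(min_value=-50, max_value=50)
        a = data.draw(st.lists(floats, min_size=2, max_size=8))
        b = data.draw(st.lists(floats, min_size=2, max_size=8))
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            return
        expected = sps.ttest_ind(a, b, equal_var=True).statistic
        assert s0_ttest(a, b, s0=0.0) == pytest.approx(expected, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            s0_ttest([1.0], [2.0, 3.0])


class TestPermutationFdr:
    def test_exhaustive_pool_size_3v3(self):
        matrix, truth = simulate_two_group_matrix(50, 3, 0, seed=0)
        result = permutation_fdr(matrix, truth["labels"], seed=0)
        # C(6,3) = 20 assignments minus the observed labeling and its mirror
        assert result.n_permutations == 18

    def test_deterministic_in_exhaustive_mode(self):
        matrix, truth = simulate_two_group_matrix(100, 3, 10, seed=1)
        r1 = permutation_fdr(matrix, truth["labels"], seed=1)
        r2 = permutation_fdr(matrix, truth["labels"], seed=99)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_same_seed_reproducible_when_sampled(self):
        matrix, truth = simulate_two_group_matrix(60, 5, 5, seed=2)
        kw = dict(n_permutations=50, fdr_threshold=0.05)
        r1 = permutation_fdr(matrix, truth["labels"], seed=7, **kw)
        r2 = permutation_fdr(matrix, truth["labels"], seed=7, **kw)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_q_values_monotone_in_statistic_magnitude(self):
        matrix, truth = simulate_two_group_matrix(200, 3, 20, seed=3)
        table = permutation_fdr(matrix, truth["labels"], seed=3).table
        ordered = table.reindex(
            table["statistic"].abs().sort_values(ascending=False).index
        )
        assert (np.diff(ordered["q_value"]) >= -1e-12).all()

    def test_site_order_invariance(self):
        matrix, truth = simulate_two_group_matrix(80, 3, 8, seed=4)
        shuffled = matrix.values.sample(frac=1.0, random_state=0)
        q1 = permutation_fdr(matrix, truth["labels"], seed=4).table["q_value"]
        q2 = permutation_fdr(shuffled, truth["labels"], seed=4).table["q_value"]
        pd.testing.assert_series_equal(q1.sort_index(), q2.sort_index())

    def test_null_false_positive_control(self):
        """Both groups from one null model: FDR < 0.01 flags ~nothing."""
        fp = []
        for seed in range(20):
            matrix, truth = simulate_two_group_matrix(
                1000, 3, 0, sd=0.25, seed=seed
            )
            result = permutation_fdr(matrix, truth["labels"], s0=0.1, seed=seed)
            fp.append(result.table["significant"].sum() / 1000)
        assert float(np.mean(fp)) < 0.05

    def test_planted_effect_recovery(self):
        """2.0 log2 shifts at sd 0.25 are recovered at FDR < 0.01."""
        matrix, truth = simulate_two_group_matrix(
            1000, 3, 100, effect_log2=2.0, sd=0.25, seed=5
        )
        result = permutation_fdr(matrix, truth["labels"], s0=0.1, seed=5)
        recovered = set(result.significant_sites) & set(truth["changed_sites"])
        assert len(recovered) >= 90

    def test_incomplete_sites_skipped(self):
        matrix, truth = simulate_two_group_matrix(10, 3, 0, seed=6)
        matrix.values.iloc[0, 0] = np.nan
        result = permutation_fdr(matrix, truth["labels"], seed=6)
        assert matrix.values.index[0] in result.skipped
        assert len(result.table) == 9


class TestProteinNormalization:
    def _site_df(self, values):
        return pd.DataFrame(values, index=["P1-S10"], columns=["r1", "r2"])

    def test_matched_fold_change_cancels(self):
        site = self._site_df([[100.0, 800.0]])
        protein = pd.DataFrame([[10.0, 80.0]], index=["P1"], columns=["r1", "r2"])
        adj, flags = normalize_site_to_protein(site, protein)
        assert adj.loc["P1-S10", "r2"] - adj.loc["P1-S10", "r1"] == pytest.approx(0.0)
        assert flags["P1-S10"]

    def test_constant_protein_preserves_differences(self):
        site = self._site_df([[100.0, 800.0]])
        protein = pd.DataFrame([[50.0, 50.0]], index=["P1"], columns=["r1", "r2"])
        adj, _ = normalize_site_to_protein(site, protein)
        assert adj.loc["P1-S10", "r2"] - adj.loc["P1-S10", "r1"] == pytest.approx(3.0)

    def test_missing_protein_passes_through_flagged(self):
        site = self._site_df([[4.0, 8.0]])
        protein = pd.DataFrame(index=["OTHER"], columns=["r1", "r2"], dtype=float)
        adj, flags = normalize_site_to_protein(site, protein)
        assert not flags["P1-S10"]
        assert adj.loc["P1-S10", "r1"] == pytest.approx(2.0)  # plain log2


class TestMotifWindows:
    PROTEINS = {"P1": "MKRRAVSPDEFGHIKLSTYVW"}

    def test_interior_site_no_padding(self):
        # S7 has exactly six flanking residues on each side
        (w,) = extract_motif_windows(["P1-S7"], self.PROTEINS)
        assert w.sequence == self.PROTEINS["P1"][:13]
        assert w.center == "S"

    def test_c_terminal_padding(self):
        # T18 sits 3 residues from the C-terminus of the 21-mer
        (w,) = extract_motif_windows(["P1-T18"], self.PROTEINS)
        assert w.sequence == "GHIKLSTYVW___"
        assert w.sequence[6] == "T"

    def test_n_terminal_padding_count(self):
        (w,) = extract_motif_windows(["P1-S6"], {"P1": "MKRRAS" + "A" * 10})
        assert w.sequence.startswith("_")
        assert w.sequence[6] == "S"

    def test_residue_mismatch_names_site(self):
        with pytest.raises(ValueError, match="P1-Y6"):
            extract_motif_windows(["P1-Y6"], self.PROTEINS)


class TestMotifEnrichment:
    @staticmethod
    def windows(seqs):
        return list(seqs)  # patterns accept raw 13-mers

    def test_no_enrichment_when_rates_match(self):
        fg = ["AAARRASAAAAAA"] * 5 + ["AAAAAASAAAAAA"] * 5
        bg = fg * 10
        table = fisher_motif_enrichment(fg, bg, patterns=DEFAULT_MOTIFS[:1])
        assert table.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert table.iloc[0]["p_value"] > 0.5

    def test_exact_hypergeometric_tail(self):
        """One-sided p equals the hypergeometric tail enumerated directly."""
        fg = ["AAARRASAAAAAA"] * 8 + ["AAAAAASAAAAAA"] * 2
        bg = ["AAARRASAAAAAA"] * 10 + ["AAAAAASAAAAAA"] * 90
        pat = MotifPattern.build("PKA", {-3: "R", -2: "R", 0: "ST"})
        table = fisher_motif_enrichment(fg, bg, patterns=[pat])
        # 2x2: fg 8/10 vs bg 10/100; tail P(X >= 8) of Hypergeom(110, 18, 10)
        expected = sps.hypergeom.sf(7, 110, 18, 10)
        assert table.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_threshold_is_strict(self):
        fg = ["AAARRASAAAAAA"] * 8 + ["AAAAAASAAAAAA"] * 2
        bg = ["AAARRASAAAAAA"] * 10 + ["AAAAAASAAAAAA"] * 90
        pat = MotifPattern.build("PKA", {-3: "R", -2: "R", 0: "ST"})
        p = fisher_motif_enrichment(fg, bg, patterns=[pat]).iloc[0]["q_value"]
        just_below = fisher_motif_enrichment(fg, bg, patterns=[pat], fdr_threshold=p)
        assert not just_below.iloc[0]["enriched"]  # FDR < threshold is strict

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_motif_enrichment([], ["AAAAAASAAAAAA"])
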