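"""Isomer enumeration, site-determining ions, Ascore-style scoring, and
per-site probability semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphodia.localization import (
    IsomerConfiguration,
    PeakList,
    classify_class1,
    enumerate_isomers,
    localize,
    score_isomers,
    site_determining_ions,
    site_probabilities,
)
from phosphodia.masscalc import fragment_ladder

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_sdi(config_a, config_b):
    """Independent oracle: build both full ladders and compare m/z elementwise."""
    la = {(f.series, f.index): f.mz for f in fragment_ladder(config_a.peptidoform())}
    lb = {(f.series, f.index): f.mz for f in fragment_ladder(config_b.peptidoform())}
    out = {"b": set(), "y": set()}
    for key in la:
        if abs(la[key] - lb[key]) > 1e-9:
            out[key[0]].add(key[1])
    return out


class TestEnumerateIsomers:
    def test_mono_count(self, egfr_peptide):
        configs = enumerate_isomers(egfr_peptide, 1)
        assert [c.positions for c in configs] == [(2,), (6,), (12,)]

    def test_di_combinations(self, egfr_peptide):
        assert [c.positions for c in enumerate_isomers(egfr_peptide, 2)] == [
            (2, 6),
            (2, 12),
            (6, 12),
        ]

    def test_excess_k_rejected(self, egfr_peptide):
        with pytest.raises(ValueError):
            enumerate_isomers(egfr_peptide, 4)


class TestSiteDeterminingIons:
    def test_egfr_s1166_vs_y1172(self, egfr_peptide):
        # peptide positions 6 vs 12 = protein S1166 vs Y1172
        a = IsomerConfiguration(egfr_peptide, (6,))
        b = IsomerConfiguration(egfr_peptide, (12,))
        sdi = site_determining_ions(a, b)
        assert sdi["b"] == set(range(6, 12))
        assert sdi["y"] == set(range(8, 14))
        # the cited confirming ions are members
        assert {8, 9} <= sdi["b"] and {8, 9} <= sdi["y"]

    def test_egfr_s1162_vs_s1166(self, egfr_peptide):
        a = IsomerConfiguration(egfr_peptide, (2,))
        b = IsomerConfiguration(egfr_peptide, (6,))
        sdi = site_determining_ions(a, b)
        assert sdi["b"] == {2, 3, 4, 5}
        assert {4, 5} <= sdi["b"]

    def test_identical_configurations(self, egfr_peptide):
        a = IsomerConfiguration(egfr_peptide, (6,))
        assert site_determining_ions(a, a) == {"b": set(), "y": set()}

    def test_mismatched_parents_rejected(self, egfr_peptide):
        a = IsomerConfiguration(egfr_peptide, (6,))
        b = IsomerConfiguration("SSTK", (1,))
        with pytest.raises(ValueError):
            site_determining_ions(a, b)

    @given(data=st.data())
    @settings(max_examples=220, derandomize=True, deadline=None)
    def test_agrees_with_ladder_comparison_oracle(self, data):
        seq = data.draw(
            st.text(alphabet=RESIDUES, min_size=6, max_size=25).filter(
                lambda s: sum(aa in "STY" for aa in s) >= 2
            )
        )
        sty = [i for i, aa in enumerate(seq, 1) if aa in "STY"]
        k = data.draw(st.integers(1, min(3, len(sty))))
        configs = enumerate_isomers(seq, k)
        ia = data.draw(st.integers(0, len(configs) - 1))
        ib = data.draw(st.integers(0, len(configs) - 1))
        assert site_determining_ions(configs[ia], configs[ib]) == brute_force_sdi(
            configs[ia], configs[ib]
        )


class TestScoreIsomers:
    def test_evidence_orders_scores(self, egfr_peptide):
        a = IsomerConfiguration(egfr_peptide, (6,))
        b = IsomerConfiguration(egfr_peptide, (12,))
        peaks = PeakList(
            tuple((f.mz, 100.0) for f in fragment_ladder(a.peptidoform()))
        )
        scores = score_isomers(peaks, [a, b])
        assert scores[(6,)] > scores[(12,)]

    def test_empty_peak_list_scores_zero(self, egfr_peptide):
        configs = enumerate_isomers(egfr_peptide, 1)
        scores = score_isomers(PeakList(()), configs)
        assert all(s == 0.0 for s in scores.values())

    def test_full_match_closed_form(self):
        # k = n = 10 matches at p = 0.01: tail = p^10, score = 200
        from phosphodia.localization import _binomial_score

        assert _binomial_score(10, 10, 0.01) == pytest.approx(200.0, abs=1e-9)

    def test_no_configurations_rejected(self):
        with pytest.raises(ValueError):
            score_isomers(PeakList(()), [])


class TestSiteProbabilities:
    def test_single_candidate_is_certain(self):
        _, site_prob = site_probabilities({(3,): 0.0})
        assert site_prob == {3: 1.0}

    def test_equal_scores_split_evenly(self):
        _, site_prob = site_probabilities({(1,): 50.0, (4,): 50.0, (9,): 50.0})
        assert all(p == pytest.approx(1 / 3) for p in site_prob.values())

    def test_di_phospho_sum_rule(self):
        scores = {(1, 4): 10.0, (1, 9): 10.0, (4, 9): 10.0}
        config_prob, site_prob = site_probabilities(scores)
        assert sum(config_prob.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p == pytest.approx(2 / 3, abs=1e-9) for p in site_prob.values())
        assert sum(site_prob.values()) == pytest.approx(2.0, abs=1e-9)

    def test_probabilities_sum_to_k_for_scored_spectra(self, egfr_peptide):
        rng = np.random.default_rng(7)
        for k in (1, 2, 3):
            configs = enumerate_isomers(egfr_peptide, k)
            target = configs[int(rng.integers(len(configs)))]
            peaks = PeakList(
                tuple((f.mz, 50 + 100 * rng.random()) for f in fragment_ladder(target.peptidoform()))
            )
            scores = score_isomers(peaks, configs)
            _, site_prob = site_probabilities(scores)
            assert sum(site_prob.values()) == pytest.approx(k, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "prob, mode, expected",
        [
            (0.75, "libDIA", True),
            (0.75, "DDA", True),
            (0.98, "dirDIA", False),
            (0.99, "dirDIA", True),
            (0.50, "DDA", False),
            (0.7499, "libDIA", False),
        ],
    )
    def test_cutoffs(self, prob, mode, expected):
        assert classify_class1(prob, mode) is expected

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            classify_class1(0.9, "SRM")


class TestAmbiguity:
    def test_removing_discriminating_peaks_restores_symmetry(self, egfr_peptide):
        """Spectra holding only shared ions leave all isomers equiprobable."""
        from phosphodia.simulate import simulate_isomer_spectra

        true = IsomerConfiguration(egfr_peptide, (6,))
        peaks, _ = simulate_isomer_spectra(
            true, coverage=1.0, seed=5, restrict_to_non_discriminating=True
        )
        result = localize(peaks, egfr_peptide, 1)
        # 3 mono configurations: each site 1/3
        for prob in result.site_probability.values():
            assert prob == pytest.approx(1 / 3, abs=1e-9)
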