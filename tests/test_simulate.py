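"""Synthetic-data generators: determinism, panel composition, noise/dropout
calibration, and spectrum ground truth."""

import numpy as np
import pandas as pd
import pytest

from phosphodia import io as pio
from phosphodia.benchmark import DilutionDesign, cv_profile, missing_value_profile
from phosphodia.localization import IsomerConfiguration, localize
from phosphodia.sitequant import rollup_phosphosites
from phosphodia.simulate import (
    DropoutModel,
    dia_window_index,
    make_fasta,
    make_panel,
    noise_sigma,
    simulate_dilution_report,
    simulate_isomer_spectra,
    simulate_two_group_matrix,
    tryptic_peptides,
)


class TestMakeFasta:
    def test_record_count_and_accessions(self):
        proteins = pio.read_fasta_text(make_fasta(5, seed=0))
        assert sorted(proteins) == [f"SIM{i}" for i in (1, 2, 3, 4, 5)]

    def test_deterministic(self):
        assert make_fasta(5, seed=3) == make_fasta(5, seed=3)
        assert make_fasta(5, seed=3) != make_fasta(5, seed=4)

    def test_fixed_length_range(self):
        proteins = pio.read_fasta_text(make_fasta(4, length_range=(20, 20), seed=0))
        assert all(len(s) == 20 for s in proteins.values())

    def test_every_protein_has_sty(self):
        proteins = pio.read_fasta_text(make_fasta(20, length_range=(20, 30), seed=1))
        assert all(set(s) & set("STY") for s in proteins.values())


class TestTrypticPeptides:
    def test_cleaves_after_k_and_r(self):
        assert tryptic_peptides("AAKGGRCC") == [(1, "AAK"), (4, "GGR"), (7, "CC")]

    def test_offsets_are_one_based_and_cover_sequence(self):
        seq = "MSSTTKYYRAAAK"
        peps = tryptic_peptides(seq)
        assert "".join(p for _, p in peps) == seq
        assert all(seq[off - 1 : off - 1 + len(p)] == p for off, p in peps)


class TestMakePanel:
    def test_default_composition_matches_benchmark_panel(self):
        fasta = make_fasta(61, seed=0)
        panel = make_panel(fasta, seed=0)
        assert len(panel) == 166
        by_mult = {m: sum(1 for e in panel if e.n_phospho == m) for m in (1, 2, 3)}
        assert by_mult == {1: 139, 2: 21, 3: 6}

    def test_small_counts_and_multiplicities(self, small_fasta):
        panel = make_panel(small_fasta, counts=(2, 1, 0), seed=0)
        assert sorted(e.n_phospho for e in panel) == [1, 1, 2]

    def test_di_on_two_sty_peptide_uses_unique_configuration(self):
        # force a single di-candidate peptide
        panel = make_panel({"SIM1": "ASTDEFGK"}, counts=(0, 1, 0), seed=0)
        assert panel[0].true_positions == (2, 3)

    def test_configurations_lie_on_sty(self, small_panel):
        for entry in small_panel:
            seq = entry.peptidoform.stripped_sequence
            assert all(seq[p - 1] in "STY" for p in entry.true_positions)

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError, match="available"):
            make_panel({"SIM1": "ASTDEFGK"}, counts=(50, 0, 0), seed=0)

    def test_deterministic(self, small_fasta):
        p1 = make_panel(small_fasta, counts=(10, 2, 1), seed=5)
        p2 = make_panel(small_fasta, counts=(10, 2, 1), seed=5)
        assert p1 == p2


class TestDilutionReport:
    def test_noiseless_areas_proportional_to_amounts(self, small_panel, small_proteins):
        design = DilutionDesign()
        records, truth = simulate_dilution_report(
            small_panel, design, noise_cv=0.0, seed=0
        )
        matrix = rollup_phosphosites(records, small_proteins)
        ref = matrix.values[design.run_ids("L2")[0]]
        for label, amount in design.levels:
            col = matrix.values[design.run_ids(label)[0]]
            assert np.allclose(col, ref * amount / 2.0, rtol=1e-12)

    def test_noise_cv_recovered(self, small_panel, small_proteins):
        design = DilutionDesign()
        records, _ = simulate_dilution_report(small_panel, design, noise_cv=0.05, seed=4)
        matrix = rollup_phosphosites(records, small_proteins)
        _, median_cv = cv_profile(matrix, design.run_ids("L2"))
        assert 3.0 < median_cv < 7.0  # wide check; the calibrated one is in acceptance

    def test_dropout_concentrates_in_lowest_level(self, small_panel):
        design = DilutionDesign()
        # midpoint above the lowest level's typical log10 abundance (~4 at L0.1)
        dropout = DropoutModel(midpoint=4.5, steepness=3.0)
        records, truth = simulate_dilution_report(
            small_panel, design, noise_cv=0.05, dropout=dropout, seed=0
        )
        dropped_runs = [run for _, run in truth.dropout_events]
        assert dropped_runs, "dropout model produced no missing observations"
        per_level = {
            label: sum(r.startswith(f"{label}_") for r in dropped_runs)
            for label, _ in design.levels
        }
        # missingness grows monotonically as the spike amount shrinks
        assert per_level["L0.1"] == max(per_level.values())
        assert per_level["L0.1"] > 2 * per_level["L2"]

    def test_ground_truth_reproducible(self, small_panel):
        r1, t1 = simulate_dilution_report(small_panel, noise_cv=0.05, seed=9)
        r2, t2 = simulate_dilution_report(small_panel, noise_cv=0.05, seed=9)
        assert t1.to_json() == t2.to_json()
        assert [r.quantity for r in r1] == [r.quantity for r in r2]

    def test_sigma_calibration(self):
        assert noise_sigma(0.05) == pytest.approx(np.sqrt(np.log(1 + 0.0025)))


class TestIsomerSpectra:
    def test_full_coverage_localizes_true_site(self, egfr_peptide):
        true = IsomerConfiguration(egfr_peptide, (6,))
        peaks, truth = simulate_isomer_spectra(true, coverage=1.0, seed=0)
        result = localize(peaks, egfr_peptide, 1)
        assert result.site_probability[6] >= 0.99
        assert truth["true_positions"] == [6]

    def test_deterministic(self, egfr_peptide):
        true = IsomerConfiguration(egfr_peptide, (2, 12))
        p1, _ = simulate_isomer_spectra(true, coverage=0.8, n_noise_peaks=5, seed=3)
        p2, _ = simulate_isomer_spectra(true, coverage=0.8, n_noise_peaks=5, seed=3)
        assert p1 == p2

    def test_coverage_controls_peak_count(self, egfr_peptide):
        true = IsomerConfiguration(egfr_peptide, (6,))
        full, _ = simulate_isomer_spectra(true, coverage=1.0, seed=0)
        half, _ = simulate_isomer_spectra(true, coverage=0.5, seed=0)
        assert len(half.peaks) == round(0.5 * len(full.peaks))


class TestTwoGroupMatrix:
    def test_null_dataset_has_no_planted_sites(self):
        matrix, truth = simulate_two_group_matrix(50, 3, 0, seed=0)
        assert truth["changed_sites"] == []
        assert matrix.values.shape == (50, 6)

    def test_planted_shift_magnitude(self):
        matrix, truth = simulate_two_group_matrix(
            500, 3, 250, effect_log2=2.0, sd=0.01, seed=1
        )
        changed = matrix.values.loc[truth["changed_sites"]]
        shift = changed[["B_R1", "B_R2", "B_R3"]].mean(axis=1) - changed[
            ["A_R1", "A_R2", "A_R3"]
        ].mean(axis=1)
        assert shift.mean() == pytest.approx(2.0, abs=0.01)

    def test_deterministic(self):
        m1, _ = simulate_two_group_matrix(20, 3, 5, seed=8)
        m2, _ = simulate_two_group_matrix(20, 3, 5, seed=8)
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestDiaWindows:
    def test_tiling(self):
        assert dia_window_index(500.0) == 0
        assert dia_window_index(509.5) == 1
        assert dia_window_index(499.0) is None
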