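"""The intensity-weighted deamidation-rate estimator and its bootstrap."""

import random

import numpy as np
import pandas as pd
import pytest

from ptmquant.deamidation import (
    DeamidationModel,
    PSMDeamidationFractions,
    bootstrap_ci,
    peptide_rate,
    psm_fractions,
    sample_rates,
)
from ptmquant.errors import DataError

from conftest import make_psm


def brute_force_rate(fractions, residue_class):
    """Independent weighted-average oracle."""
    pairs = [
        (f.ratio(residue_class), f.intensity)
        for f in fractions
        if f.ratio(residue_class) is not None and f.intensity is not None
    ]
    total = sum(w for _, w in pairs)
    return sum(r * w for r, w in pairs) / total


def random_fractions(rng, n):
    out = []
    for _ in range(n):
        num_n = rng.randint(0, 4)
        num_q = rng.randint(0, 3)
        out.append(
            PSMDeamidationFractions(
                num_N=num_n,
                num_N2D=rng.randint(0, num_n) if num_n else 0,
                num_Q=num_q,
                num_Q2E=rng.randint(0, num_q) if num_q else 0,
                intensity=rng.uniform(1e3, 1e8),
            )
        )
    return out


class TestPsmFractions:
    def test_half_deamidated(self):
        record = make_psm("ANGANK", deamidated_positions=(2,))
        frac = psm_fractions(record)
        assert (frac.num_N, frac.num_N2D) == (2, 1)
        assert frac.ratio_N2D == 0.5

    def test_unmodified_peptide_has_zero_ratio(self):
        frac = psm_fractions(make_psm("ANGANK"))
        assert frac.ratio_N2D == 0.0

    def test_class_without_residues_is_undefined(self):
        frac = psm_fractions(make_psm("AGLK"))
        assert frac.ratio_N2D is None and frac.ratio_Q2E is None

    def test_counts_match_brute_force_residue_scan(self):
        rng = random.Random(7)
        for _ in range(25):
            sequence = "".join(rng.choice("ANQGK") for _ in range(12))
            deam = tuple(
                p for p, aa in enumerate(sequence, 1)
                if aa in "NQ" and rng.random() < 0.4
            )
            frac = psm_fractions(make_psm(sequence, deam))
            assert frac.num_N == sequence.count("N")
            assert frac.num_Q == sequence.count("Q")
            assert frac.num_N2D == sum(1 for p in deam if sequence[p - 1] == "N")
            assert frac.num_Q2E == sum(1 for p in deam if sequence[p - 1] == "Q")


class TestPeptideRate:
    def test_symmetric_two_psm_group(self):
        fractions = [
            PSMDeamidationFractions(1, 1, 0, 0, 1e6),
            PSMDeamidationFractions(1, 0, 0, 0, 1e6),
        ]
        assert peptide_rate(fractions, "N") == 0.5

    def test_all_unmodified_is_zero(self):
        fractions = [PSMDeamidationFractions(2, 0, 1, 0, 1e5)] * 4
        assert peptide_rate(fractions, "N") == 0.0
        assert peptide_rate(fractions, "Q") == 0.0

    def test_missing_intensities_excluded_from_weighting(self):
        fractions = [
            PSMDeamidationFractions(1, 1, 0, 0, None),
            PSMDeamidationFractions(1, 0, 0, 0, 1e6),
        ]
        assert peptide_rate(fractions, "N") == 0.0

    def test_all_intensities_missing_is_undefined(self):
        with pytest.raises(DataError):
            peptide_rate([PSMDeamidationFractions(1, 1, 0, 0, None)], "N")

    def test_matches_brute_force_oracle_on_random_groups(self):
        rng = random.Random(1218)
        checked = 0
        while checked < 50:
            fractions = random_fractions(rng, rng.randint(1, 12))
            for residue_class in "NQ":
                if not any(
                    f.ratio(residue_class) is not None for f in fractions
                ):
                    continue
                assert peptide_rate(fractions, residue_class) == pytest.approx(
                    brute_force_rate(fractions, residue_class), abs=1e-12
                )
                checked += 1


class TestSampleRates:
    def test_charge_states_averaged_unweighted(self):
        records = [
            make_psm("ANGK", (2,), charge=2, intensity=1e6),
            make_psm("ANGK", charge=2, intensity=4e6),  # z2 rate 0.2
            make_psm("ANGK", (2,), charge=3, intensity=2e6),
            make_psm("ANGK", charge=3, intensity=3e6),  # z3 rate 0.4
        ]
        rates = sample_rates(records, "run_01", "N")
        assert rates["ANGK"] == pytest.approx(0.3)

    def test_two_level_average_matches_brute_force(self):
        rng = random.Random(99)
        records = []
        for seq in ("ANGK", "NNTAK", "AQGNK"):
            for charge in (2, 3):
                for _ in range(rng.randint(1, 6)):
                    deam = tuple(
                        p for p, aa in enumerate(seq, 1)
                        if aa in "NQ" and rng.random() < 0.5
                    )
                    records.append(
                        make_psm(seq, deam, charge=charge,
                                 intensity=rng.uniform(1e4, 1e7))
                    )
        rates = sample_rates(records, "run_01", "N")
        for seq in ("ANGK", "NNTAK", "AQGNK"):
            per_charge = []
            for charge in (2, 3):
                group = [
                    psm_fractions(r)
                    for r in records
                    if r.sequence == seq and r.charge == charge
                ]
                if group:
                    per_charge.append(brute_force_rate(group, "N"))
            assert rates[seq] == pytest.approx(
                sum(per_charge) / len(per_charge), abs=1e-12
            )


class TestBootstrap:
    def test_all_zero_values_give_all_zero_summary(self):
        mean, sd, lo, hi, draws = bootstrap_ci([0.0] * 8, seed=3)
        assert (mean, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)
        assert not draws.any()

    def test_single_value_is_degenerate(self):
        mean, sd, lo, hi, _ = bootstrap_ci([0.37], seed=3)
        assert mean == pytest.approx(0.37)
        assert sd == 0.0 and lo == pytest.approx(0.37) and hi == pytest.approx(0.37)

    def test_reproducible_given_seed(self):
        values = list(np.random.default_rng(5).random(20))
        first = bootstrap_ci(values, seed=11)
        second = bootstrap_ci(values, seed=11)
        assert first[:4] == second[:4]
        assert (first[4] == second[4]).all()

    def test_bootstrap_mean_tracks_sample_mean(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0.3, 0.1, size=200)
        mean, sd, lo, hi, _ = bootstrap_ci(values, n_boot=2000, seed=4)
        se = values.std(ddof=1) / np.sqrt(values.size)
        assert abs(mean - values.mean()) < 3 * se
        assert lo < values.mean() < hi

    def test_interval_coverage_near_nominal(self):
        # CI coverage of the true mean ~95% over repeated draws
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 300
        for _ in range(reps):
            sample = rng.normal(0.5, 0.2, size=40)
            _, _, lo, hi, _ = bootstrap_ci(sample, n_boot=400, seed=rng)
            hits += lo <= 0.5 <= hi
        assert 0.88 <= hits / reps <= 0.99


class TestModelResults:
    def build_records(self):
        return [
            make_psm("ANGK", (2,), intensity=2e6),
            make_psm("ANGK", intensity=2e6),
            make_psm("AQGK", intensity=1e6),
            make_psm("NNTAK", intensity=5e5),
        ]

    def test_fit_reports_percent_scale_rates(self):
        fit = DeamidationModel(self.build_records()).fit(n_boot=200, seed=8)
        n_row = fit.table[
            (fit.table["Raw file"] == "run_01") & (fit.table["Residue"] == "N")
        ].iloc[0]
        # peptide rates: ANGK 0.5, NNTAK 0 -> sample mean 25%
        assert fit.sample_mean("run_01", "N") == pytest.approx(25.0)
        assert 0 <= n_row["CI_low"] <= n_row["CI_up"] <= 100
        assert n_row["N_scans"] == 3

    def test_record_and_dataframe_inputs_agree(self):
        records = self.build_records()
        frame = pd.DataFrame(
            {
                "Sequence": [r.sequence for r in records],
                "Modified sequence": [r.modified_sequence for r in records],
                "Charge": [r.charge for r in records],
                "Intensity": [r.intensity for r in records],
                "Raw file": [r.raw_file for r in records],
                "Leading razor protein": [r.leading_razor_protein for r in records],
            }
        )
        fit_records = DeamidationModel(records).fit(n_boot=100, seed=8)
        fit_frame = DeamidationModel(frame).fit(n_boot=100, seed=8)
        pd.testing.assert_frame_equal(fit_records.table, fit_frame.table)

    def test_row_order_does_not_change_results(self):
        records = self.build_records()
        shuffled = list(records)
        random.Random(3).shuffle(shuffled)
        a = DeamidationModel(records).fit(n_boot=150, seed=9)
        b = DeamidationModel(shuffled).fit(n_boot=150, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_intensity_scale_invariance(self):
        records = self.build_records()
        scaled = [
            make_psm(r.sequence,
                     tuple(p for _, p in r.modifications),
                     charge=r.charge,
                     intensity=r.intensity * 137.0)
            for r in records
        ]
        a = DeamidationModel(records).fit(n_boot=150, seed=9)
        b = DeamidationModel(scaled).fit(n_boot=150, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_rates_stay_in_unit_interval(self):
        fit = DeamidationModel(self.build_records()).fit(n_boot=100, seed=8)
        assert ((fit.peptide_rates["Rate"] >= 0)
                & (fit.peptide_rates["Rate"] <= 1)).all()
        assert ((fit.table["Mean"] >= 0) & (fit.table["Mean"] <= 100)).all()

    def test_summary_mentions_bootstrap_settings(self):
        fit = DeamidationModel(self.build_records()).fit(n_boot=100, seed=8)
        text = fit.summary()
        assert "n_boot=100" in text and "seed=8" in text

    def test_output_files_written_with_expected_shapes(self, tmp_path):
        fit = DeamidationModel(self.build_records()).fit(n_boot=50, seed=8)
        paths = fit.to_files(tmp_path, header_comment="test run")
        names = {p.name for p in paths}
        assert names == {
            "Deamidation.txt",
            "Number_of_Peptides_per_RawFile.txt",
            "Bootstrapped_values.txt",
            "Protein_deamidation.txt",
        }
        deam = pd.read_csv(tmp_path / "Deamidation.txt", sep="\t", comment="#")
        assert len(deam) == 2  # one raw file x {N, Q}
        boot = pd.read_csv(
            tmp_path / "Bootstrapped_values.txt", sep="\t", comment="#"
        )
        assert len(boot) == 50 * 2  # n_boot per raw file per residue class
        protein = pd.read_csv(
            tmp_path / "Protein_deamidation.txt", sep="\t", comment="#"
        )
        assert set(protein["Protein"]) == {"P1"}

    def test_zero_deamidation_controls_are_all_zero(self, tmp_path):
        records = [
            make_psm("ANGK", intensity=1e6, raw_file="NSC34_rep1"),
            make_psm("AQGK", intensity=2e6, raw_file="NSC34_rep1"),
        ]
        fit = DeamidationModel(records).fit(n_boot=100, seed=5)
        assert (fit.table[["Mean", "Std", "CI_low", "CI_up"]] == 0).all().all()
        fit.to_files(tmp_path)
        written = pd.read_csv(tmp_path / "Deamidation.txt", sep="\t")
        assert (written[["Mean", "Std", "CI_low", "CI_up"]] == 0).all().all()
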