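"""Evidence-table and FASTA I/O: parsing dialects, round trips, errors."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmquant.errors import ConfigurationError, DataError, EvidenceParseError
from ptmquant.evidence import (
    DEFAULT_DIALECT,
    PSMRecord,
    modification_counts_from_summary,
    parse_modified_sequence,
    read_evidence,
    read_fasta,
    write_evidence,
)

EVIDENCE_HEADER = "\t".join(
    ["Sequence", "Modified sequence", "Modifications", "Charge", "m/z",
     "Intensity", "Raw file", "Proteins", "Leading razor protein"]
)


def evidence_file(tmp_path, rows, header=EVIDENCE_HEADER):
    path = tmp_path / "evidence.txt"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestParseModifiedSequence:
    @pytest.mark.parametrize(
        "modseq, expected_mods",
        [
            ("_TKSEN(de)GLEFTSSGSANTETTK_", (("deamidation", 5),)),
            ("_TKSEN(Deamidation (NQ))GLEFTSSGSANTETTK_", (("deamidation", 5),)),
            ("TKSEN[+0.98402]GLEFTSSGSANTETTK", (("deamidation", 5),)),
            ("_TKSENGLEFTSSGSANTETTK_", ()),
            (
                "_TKSEN(de)GLEFTSSGSAN(de)TETTK_",
                (("deamidation", 5), ("deamidation", 16)),
            ),
        ],
    )
    def test_token_dialects(self, registry, modseq, expected_mods):
        plain, mods = parse_modified_sequence(modseq, registry)
        assert plain == "TKSENGLEFTSSGSANTETTK"
        assert mods == expected_mods

    def test_nterm_token_is_position_zero(self, registry):
        plain, mods = parse_modified_sequence("_(ac)MAVPK_", registry)
        assert plain == "MAVPK"
        assert mods == (("acetyl", 0),)

    def test_unknown_token_names_the_token(self, registry):
        with pytest.raises(ConfigurationError, match="nonsense"):
            parse_modified_sequence("_AN(nonsense)K_", registry)

    def test_token_on_non_target_residue_rejected(self, registry):
        with pytest.raises(EvidenceParseError, match="does not target"):
            parse_modified_sequence("_AG(de)K_", registry)

    def test_summary_column_parser(self):
        counts = modification_counts_from_summary(
            "2 Deamidation (NQ); Oxidation (M)"
        )
        assert counts == {"Deamidation (NQ)": 2, "Oxidation (M)": 1}
        assert modification_counts_from_summary("Unmodified") == {}


class TestReadEvidence:
    def test_header_only_file_gives_empty_list(self, tmp_path):
        assert read_evidence(evidence_file(tmp_path, [])) == []

    def test_published_deamidated_psm_row(self, tmp_path):
        # the N37-deamidated tryptic peptide with its printed intensity
        path = evidence_file(
            tmp_path,
            ["TKSENGLEFTSSGSANTETTK\t_TKSEN(de)GLEFTSSGSANTETTK_\t"
             "Deamidation (NQ)\t3\t730.6730\t6.3e6\trep1\tVDAC1\tVDAC1"],
        )
        (record,) = read_evidence(path)
        assert record.charge == 3
        assert record.intensity == pytest.approx(6.3e6)
        assert record.modifications == (("deamidation", 5),)

    def test_missing_intensity_kept_as_none(self, tmp_path):
        path = evidence_file(
            tmp_path, ["PEPTIDEK\t_PEPTIDEK_\tUnmodified\t2\t\t\trep1\tP1\tP1"]
        )
        (record,) = read_evidence(path)
        assert record.intensity is None

    def test_column_order_is_irrelevant(self, tmp_path):
        shuffled = "\t".join(
            ["Raw file", "Intensity", "Charge", "Modified sequence", "Sequence"]
        )
        path = evidence_file(
            tmp_path,
            ["rep1\t5e5\t2\t_PEPTIDEK_\tPEPTIDEK"],
            header=shuffled,
        )
        (record,) = read_evidence(path)
        assert record.sequence == "PEPTIDEK" and record.raw_file == "rep1"

    def test_missing_required_column_names_it(self, tmp_path):
        path = evidence_file(
            tmp_path, ["_PEPTIDEK_\t2\t1e5\trep1"],
            header="Modified sequence\tCharge\tIntensity\tRaw file",
        )
        with pytest.raises(ConfigurationError, match="Sequence"):
            read_evidence(path)

    def test_dialect_mapping_renames_columns(self, tmp_path):
        header = "\t".join(["seq", "modseq", "z", "inten", "file"])
        path = evidence_file(
            tmp_path, ["PEPTIDEK\t_PEPTIDEK_\t2\t1e5\trep1"], header=header
        )
        records = read_evidence(
            path,
            dialect={"sequence": "seq", "modified_sequence": "modseq",
                     "charge": "z", "intensity": "inten", "raw_file": "file"},
        )
        assert records[0].sequence == "PEPTIDEK"

    def test_non_numeric_charge_reports_line(self, tmp_path):
        path = evidence_file(
            tmp_path,
            ["PEPTIDEK\t_PEPTIDEK_\tUnmodified\t2\t\t1e5\trep1\tP1\tP1",
             "PEPTIDEK\t_PEPTIDEK_\tUnmodified\ttwo\t\t1e5\trep1\tP1\tP1"],
        )
        with pytest.raises(EvidenceParseError, match="line 3"):
            read_evidence(path)

    def test_summary_count_mismatch_rejected(self, tmp_path):
        path = evidence_file(
            tmp_path,
            ["ANK\t_AN(de)K_\t2 Deamidation (NQ)\t2\t\t1e5\trep1\tP1\tP1"],
        )
        with pytest.raises(EvidenceParseError, match="implies 2"):
            read_evidence(path)


psm_records = st.builds(
    PSMRecord,
    raw_file=st.sampled_from(["run_01", "run_02"]),
    sequence=st.just("TKSENGLEFTSSGSANTETTK"),
    modified_sequence=st.just("_TKSEN(de)GLEFTSSGSANTETTK_"),
    modifications=st.just((("deamidation", 5),)),
    charge=st.integers(min_value=1, max_value=4),
    observed_mz=st.one_of(st.none(), st.floats(min_value=200, max_value=2000)),
    intensity=st.one_of(st.none(), st.floats(min_value=0, max_value=1e9)),
    proteins=st.just(("VDAC1",)),
    leading_razor_protein=st.just("VDAC1"),
)


class TestRoundTrip:
    @given(st.lists(psm_records, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_write_then_read_is_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "evidence.txt"
        write_evidence(records, path)
        assert read_evidence(path) == records


class TestPSMRecordInvariants:
    def test_non_canonical_sequence_rejected(self):
        with pytest.raises(DataError):
            PSMRecord(raw_file="r", sequence="AB1", modified_sequence="_AB1_")

    def test_negative_intensity_rejected(self):
        with pytest.raises(DataError):
            PSMRecord(raw_file="r", sequence="AK", modified_sequence="_AK_",
                      intensity=-1.0)

    def test_out_of_range_modification_position_rejected(self):
        with pytest.raises(DataError):
            PSMRecord(raw_file="r", sequence="AK", modified_sequence="_AK_",
                      modifications=(("deamidation", 9),))


class TestFasta:
    def test_simple_entry(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1 test protein\nACDE\n")
        (entry,) = read_fasta(path)
        assert entry.accession == "P1" and entry.sequence == "ACDE"

    def test_wrapped_lines_reconstructed(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nACDE\nFGHI\n>P2\nKLMN\nPQRS\n")
        entries = read_fasta(path)
        assert [e.sequence for e in entries] == ["ACDEFGHI", "KLMNPQRS"]

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nACDE\n>P1\nKLMN\n")
        with pytest.raises(DataError, match="duplicate"):
            read_fasta(path)

    def test_invalid_letter_named(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1\nACDZE\n")
        with pytest.raises(DataError, match="Z"):
            read_fasta(path)

    def test_packaged_scaffold_pins_the_study_features(self, vdac1):
        seq = vdac1.sequence
        assert len(seq) == 283 and seq[0] == "M" and seq[1] == "A"
        assert seq[154] == "M" and seq[126] == "C" and seq[231] == "C"
        for residue, pos in [("N", 37), ("N", 106), ("Q", 166), ("N", 207),
                             ("N", 214), ("Q", 226), ("N", 239)]:
            assert seq[pos - 1] == residue


def test_default_dialect_covers_required_fields():
    assert {"sequence", "modified_sequence", "charge", "intensity",
            "raw_file"} <= set(DEFAULT_DIALECT)
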