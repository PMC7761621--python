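"""Evidence-table and FASTA I/O.

Reads PSM-level evidence in the MaxQuant ``evidence.txt`` tab-delimited
dialect into :class:`PSMRecord` objects, resolving inline modification tokens
in the "Modified sequence" column so that a deamidation is attributed to the
specific N or Q residue that carries it.  Also writes the four delimited
output files of the deamidation analysis.

Only column *names* matter, never their order; a dialect mapping can rename
them for other search-engine exports.  Numbers use "." as decimal point and
scientific notation is accepted on input.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .constants import CANONICAL_RESIDUES, FASTA_RESIDUES
from .errors import ConfigurationError, DataError, EvidenceParseError
from .modifications import ModificationRegistry, default_registry

#: Canonical field -> column header in the MaxQuant evidence dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "sequence": "Sequence",
    "modified_sequence": "Modified sequence",
    "modifications": "Modifications",
    "charge": "Charge",
    "mz": "m/z",
    "intensity": "Intensity",
    "raw_file": "Raw file",
    "proteins": "Proteins",
    "leading_razor_protein": "Leading razor protein",
}

REQUIRED_FIELDS = ("sequence", "modified_sequence", "charge", "intensity", "raw_file")


@dataclass(frozen=True)
class ProteinEntry:
    """One FASTA entry: accession, free-text description, residue string."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"protein {self.accession!r} has an empty sequence")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``modifications`` is a tuple of ``(modification name, position)`` pairs
    with one-based positions into ``sequence`` (0 marks the N-terminus).
    ``intensity`` is ``None`` when the evidence row had no intensity; such
    records still count as scans but carry no weight in intensity-weighted
    statistics.
    """

    raw_file: str
    sequence: str
    modified_sequence: str
    modifications: tuple = ()
    charge: int = 2
    observed_mz: Optional[float] = None
    intensity: Optional[float] = None
    proteins: tuple = ()
    leading_razor_protein: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise DataError("PSM with empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise DataError(
                f"PSM sequence {self.sequence!r} contains non-canonical "
                f"letters {sorted(bad)}"
            )
        if self.charge < 1:
            raise DataError(f"charge must be >= 1, got {self.charge}")
        if self.intensity is not None and not self.intensity >= 0:
            raise DataError(f"negative intensity {self.intensity}")
        for name, pos in self.modifications:
            if not 0 <= pos <= len(self.sequence):
                raise DataError(
                    f"modification {name!r} at position {pos} outside "
                    f"0..{len(self.sequence)}"
                )

    def count_modification(self, name: str) -> int:
        return sum(1 for n, _ in self.modifications if n == name)

    def modified_positions(self, name: str) -> tuple:
        return tuple(p for n, p in self.modifications if n == name)


# ---------------------------------------------------------------------------
# Modified-sequence token parsing
# ---------------------------------------------------------------------------

def parse_modified_sequence(
    modified_sequence: str, registry: ModificationRegistry
) -> tuple:
    """Split a "Modified sequence" string into (plain sequence, modifications).

    Accepts the MaxQuant underscore-wrapped dialect with parenthesised tokens
    after the modified residue — short (``(de)``) or long, possibly nested
    (``(Deamidation (NQ))``) — and the bracketed numeric dialect
    (``N[+0.98402]``), resolved against the registry by nearest delta.  A
    token before the first residue letter is an N-terminal modification
    (position 0).
    """
    text = modified_sequence.strip().strip("_")
    sequence: list[str] = []
    mods: list[tuple] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth, j = 1, i + 1
            while j < len(text) and depth:
                depth += {"(": 1, ")": -1}.get(text[j], 0)
                j += 1
            if depth:
                raise EvidenceParseError(
                    f"unbalanced parenthesis in {modified_sequence!r}"
                )
            spec = registry.resolve_token(text[i + 1 : j - 1])
            mods.append((spec.name, len(sequence)))
            i = j
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise EvidenceParseError(f"unbalanced bracket in {modified_sequence!r}")
            try:
                delta = float(text[i + 1 : j])
            except ValueError:
                raise EvidenceParseError(
                    f"non-numeric mass token {text[i + 1 : j]!r} in "
                    f"{modified_sequence!r}"
                ) from None
            spec = registry.resolve_delta(delta)
            mods.append((spec.name, len(sequence)))
            i = j + 1
        elif ch.isalpha():
            sequence.append(ch.upper())
            i += 1
        else:
            raise EvidenceParseError(
                f"unexpected character {ch!r} in {modified_sequence!r}"
            )
    plain = "".join(sequence)
    for name, pos in mods:
        spec = registry.get(name)
        if pos == 0:
            continue  # terminal; placement checked by the registry consumer
        if not spec.targets_residue(plain[pos - 1]):
            raise EvidenceParseError(
                f"modification {name!r} sits on residue {plain[pos - 1]!r} "
                f"at position {pos}, which it does not target "
                f"(in {modified_sequence!r})"
            )
    return plain, tuple(mods)


_SUMMARY_ITEM = re.compile(r"^\s*(?:(\d+)\s+)?(.+?)\s*$")


def modification_counts_from_summary(summary: str) -> dict:
    """Parse a "Modifications" summary like ``2 Deamidation (NQ); Oxidation (M)``.

    Returns a mapping of raw modification label -> count.  ``Unmodified``
    yields an empty mapping.
    """
    summary = (summary or "").strip()
    if not summary or summary.lower() == "unmodified":
        return {}
    counts: dict[str, int] = {}
    for item in summary.split(";"):
        m = _SUMMARY_ITEM.match(item)
        if not m or not m.group(2):
            raise EvidenceParseError(f"cannot parse modification summary {summary!r}")
        counts[m.group(2)] = counts.get(m.group(2), 0) + int(m.group(1) or 1)
    return counts


# ---------------------------------------------------------------------------
# Evidence reading / writing
# ---------------------------------------------------------------------------

def _resolve_dialect(dialect: Optional[Mapping[str, str]]) -> dict:
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(
                f"unknown dialect field(s) {sorted(unknown)}; expected a subset "
                f"of {sorted(DEFAULT_DIALECT)}"
            )
        mapping.update(dialect)
    return mapping


def _parse_float(value, what: str, line: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    try:
        return float(text)
    except ValueError:
        raise EvidenceParseError(f"non-numeric {what} {text!r}", line=line) from None


def read_evidence(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    registry: Optional[ModificationRegistry] = None,
    check_summary: bool = True,
) -> list[PSMRecord]:
    """Read a tab-delimited evidence table into a list of :class:`PSMRecord`.

    Rows with an empty Intensity cell are kept with ``intensity=None``.  When
    both the "Modified sequence" tokens and the "Modifications" summary column
    are present, their per-name counts are cross-checked.
    """
    registry = registry or default_registry()
    mapping = _resolve_dialect(dialect)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fieldname in REQUIRED_FIELDS:
        if mapping[fieldname] not in frame.columns:
            raise ConfigurationError(
                f"evidence table {path} is missing required column "
                f"{mapping[fieldname]!r} (field {fieldname!r})"
            )
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        line = i + 2  # 1-based, after the header row
        charge_text = row[mapping["charge"]].strip()
        try:
            charge = int(float(charge_text))
            if charge != float(charge_text):
                raise ValueError
        except ValueError:
            raise EvidenceParseError(
                f"non-numeric charge {charge_text!r}", line=line
            ) from None
        plain, mods = parse_modified_sequence(row[mapping["modified_sequence"]], registry)
        stated = row[mapping["sequence"]].strip().upper()
        if stated and plain != stated:
            raise EvidenceParseError(
                f"modified sequence strips to {plain!r} but Sequence column "
                f"says {stated!r}",
                line=line,
            )
        summary_col = mapping["modifications"]
        if check_summary and summary_col in frame.columns:
            summary = modification_counts_from_summary(row[summary_col])
            if summary:
                parsed_total = len(mods)
                summary_total = sum(summary.values())
                if parsed_total != summary_total:
                    raise EvidenceParseError(
                        f"{parsed_total} inline modification token(s) but the "
                        f"Modifications column implies {summary_total}",
                        line=line,
                    )
        proteins_text = row.get(mapping["proteins"], "")
        proteins = tuple(p for p in proteins_text.split(";") if p) if proteins_text else ()
        records.append(
            PSMRecord(
                raw_file=row[mapping["raw_file"]].strip(),
                sequence=plain,
                modified_sequence=row[mapping["modified_sequence"]].strip(),
                modifications=mods,
                charge=charge,
                observed_mz=_parse_float(row.get(mapping["mz"]), "m/z", line),
                intensity=_parse_float(row.get(mapping["intensity"]), "intensity", line),
                proteins=proteins,
                leading_razor_protein=row.get(mapping["leading_razor_protein"], "").strip(),
            )
        )
    return records


def _format_float(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_evidence(
    records: Iterable[PSMRecord], path, dialect: Optional[Mapping[str, str]] = None
) -> None:
    """Write records as a tab-delimited evidence table (lossless round-trip)."""
    mapping = _resolve_dialect(dialect)
    rows = []
    for rec in records:
        rows.append(
            {
                mapping["sequence"]: rec.sequence,
                mapping["modified_sequence"]: rec.modified_sequence,
                mapping["charge"]: rec.charge,
                mapping["mz"]: _format_float(rec.observed_mz),
                mapping["intensity"]: _format_float(rec.intensity),
                mapping["raw_file"]: rec.raw_file,
                mapping["proteins"]: ";".join(rec.proteins),
                mapping["leading_razor_protein"]: rec.leading_razor_protein,
            }
        )
    columns = [mapping[f] for f in ("sequence", "modified_sequence", "charge",
                                    "mz", "intensity", "raw_file", "proteins",
                                    "leading_razor_protein")]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinEntry]:
    """Read a FASTA file; accession is the first header token, sequences are
    uppercased with whitespace/gaps removed.  Duplicate accessions and
    non-canonical letters (other than X) are errors."""
    entries: list[ProteinEntry] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise DataError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(record.seq).upper().replace("-", "").replace(".", "")
        bad = set(sequence) - FASTA_RESIDUES
        if bad:
            raise DataError(
                f"protein {accession!r} contains invalid letter(s) {sorted(bad)}"
            )
        entries.append(ProteinEntry(accession, record.description, sequence))
    return entries


# ---------------------------------------------------------------------------
# Deamidation output files
# ---------------------------------------------------------------------------

DEAMIDATION_FILES = (
    "Deamidation.txt",
    "Number_of_Peptides_per_RawFile.txt",
    "Bootstrapped_values.txt",
    "Protein_deamidation.txt",
)


def _write_table(frame: pd.DataFrame, path: Path, header_comment: Optional[str]):
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_deamidation_outputs(
    results, out_dir, header_comment: Optional[str] = None
) -> list[Path]:
    """Write the four delimited deamidation output files.

    ``results`` is a fitted :class:`~ptmquant.deamidation.DeamidationResults`.
    Files: per raw-file/residue-class summary (mean %, SD, 95% CI bounds,
    scan count), peptide tallies per raw file, every bootstrap draw, and the
    same summary aggregated per protein accession.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [out_dir / name for name in DEAMIDATION_FILES]

    _write_table(results.table, paths[0], header_comment)
    _write_table(results.peptide_counts, paths[1], header_comment)

    boot_rows = []
    for (raw_file, residue), draws in results.bootstrap_draws.items():
        for iteration, value in enumerate(draws, start=1):
            boot_rows.append(
                {"Raw file": raw_file, "Residue": residue,
                 "Iteration": iteration, "Value": value}
            )
    _write_table(
        pd.DataFrame(boot_rows, columns=["Raw file", "Residue", "Iteration", "Value"]),
        paths[2],
        header_comment,
    )
    _write_table(results.protein_table, paths[3], header_comment)
    return paths
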