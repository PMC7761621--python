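"""Protein sequence coverage from identified peptides.

Peptides are located as exact substrings of the protein and reported as
1-based inclusive intervals in *precursor* numbering, i.e. counting the
initiator methionine even when it is removed from the mature chain.  The
coverage fraction is computed over the mature range only: with the initiator
Met removed the mature chain spans positions ``mature_offset .. length``, so
a 283-residue precursor with Met1 cleaved has a 282-residue denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Tuple

from .errors import DataError
from .evidence import ProteinEntry

Interval = Tuple[int, int]


class LocateResult(NamedTuple):
    """Located peptide intervals plus the peptides that matched nowhere."""

    intervals: list  # (peptide, start, end) per occurrence
    unmatched: list  # peptides with no exact occurrence


@dataclass(frozen=True)
class CoverageMap:
    """Covered/uncovered residue intervals of one protein.

    ``covered`` and ``uncovered`` are sorted, non-overlapping, 1-based
    inclusive intervals that partition the mature range
    ``[mature_offset, precursor_length]`` exactly.
    """

    accession: str
    precursor_length: int
    mature_offset: int
    covered: tuple
    uncovered: tuple
    coverage_fraction: float

    @property
    def mature_length(self) -> int:
        return self.precursor_length - self.mature_offset + 1

    @property
    def covered_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.covered)


def locate_peptides(
    protein: ProteinEntry, peptides: Iterable[str]
) -> LocateResult:
    """Every exact occurrence of every peptide as a precursor-numbering interval.

    A peptide occurring more than once yields one interval per occurrence;
    peptides with no occurrence are collected in ``unmatched`` rather than
    silently dropped.
    """
    sequence = protein.sequence
    intervals, unmatched = [], []
    for peptide in peptides:
        if not peptide:
            raise DataError("empty peptide in coverage query")
        found = False
        start = sequence.find(peptide)
        while start >= 0:
            intervals.append((peptide, start + 1, start + len(peptide)))
            found = True
            start = sequence.find(peptide, start + 1)
        if not found:
            unmatched.append(peptide)
    return LocateResult(intervals, unmatched)


def merge_intervals(intervals: Iterable[Interval]) -> tuple:
    """Merge overlapping *and adjacent* 1-based inclusive intervals."""
    ordered = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ordered:
        if s > e:
            raise DataError(f"invalid interval ({s}, {e})")
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def compute_coverage(
    intervals: Sequence[Interval],
    precursor_length: int,
    mature_offset: int = 1,
    accession: str = "",
) -> CoverageMap:
    """Merge intervals and compute the coverage fraction over the mature range.

    Intervals are given in precursor numbering.  An interval reaching below
    ``mature_offset`` (e.g. one that nominally includes a cleaved initiator
    Met) is clipped to the mature range; intervals outside ``1..length`` are
    errors.
    """
    if not 1 <= mature_offset <= precursor_length:
        raise DataError(
            f"mature_offset {mature_offset} outside 1..{precursor_length}"
        )
    clipped = []
    for s, e in intervals:
        if s < 1 or e > precursor_length or s > e:
            raise DataError(
                f"interval ({s}, {e}) out of bounds for precursor length "
                f"{precursor_length}"
            )
        s = max(s, mature_offset)
        if s <= e:
            clipped.append((s, e))
    covered = merge_intervals(clipped)
    mature_length = precursor_length - mature_offset + 1
    covered_residues = sum(e - s + 1 for s, e in covered)
    uncovered = []
    cursor = mature_offset
    for s, e in covered:
        if s > cursor:
            uncovered.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= precursor_length:
        uncovered.append((cursor, precursor_length))
    return CoverageMap(
        accession=accession,
        precursor_length=precursor_length,
        mature_offset=mature_offset,
        covered=covered,
        uncovered=tuple(uncovered),
        coverage_fraction=covered_residues / mature_length,
    )


def coverage_map(
    protein: ProteinEntry, peptides: Iterable[str], mature_offset: int = 1
) -> CoverageMap:
    """Locate peptides and compute coverage in one call."""
    located = locate_peptides(protein, peptides)
    return compute_coverage(
        [(s, e) for _, s, e in located.intervals],
        precursor_length=len(protein),
        mature_offset=mature_offset,
        accession=protein.accession,
    )


def format_coverage_report(cov: CoverageMap) -> str:
    """Plain-text report of covered/uncovered runs and the coverage fraction."""
    lines = [
        f"Protein: {cov.accession}",
        f"Precursor length: {cov.precursor_length} "
        f"(mature {cov.mature_length}, first mature residue {cov.mature_offset})",
        f"Coverage: {cov.covered_residues}/{cov.mature_length} residues "
        f"({100 * cov.coverage_fraction:.1f}%)",
        "Covered: " + ", ".join(f"{s}-{e}" for s, e in cov.covered),
        "Uncovered: "
        + (", ".join(f"{s}-{e}" for s, e in cov.uncovered) or "(none)"),
    ]
    return "\n".join(lines)
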