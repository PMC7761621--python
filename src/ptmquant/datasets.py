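"""Packaged example data.

Two kinds of fixtures ship with the package:

*  Transcriptions of the published summary tables of the VDAC1 PTM study —
   the per-replicate molecular-ion intensities of the sulfur-peptide and
   deamidated-peptide pairs, and the per-cell-line mean LFQ intensities of
   the three VDAC paralogs.  These printed numbers are *inputs* to the ratio
   and share computations.

*  A synthetic three-paralog FASTA.  The real SwissProt sequences are not
   bundled; ``vdac_synthetic.fasta`` is a constructed stand-in whose VDAC1
   entry embeds every published peptide at its published coordinates (283
   residues with initiator Met, the seven deamidation-site residues, Met155,
   Cys127/Cys232, and the published uncovered runs flanked by tryptic
   sites).  It supports coverage arithmetic and simulation, not homology
   searches.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coverage import merge_intervals
from .evidence import ProteinEntry, read_fasta
from .occupancy import PeptideForm

#: Precursor length and first mature residue of the VDAC1-like scaffold
#: (initiator Met removed during maturation).
VDAC1_PRECURSOR_LENGTH = 283
VDAC1_MATURE_OFFSET = 2

#: Residues of the mature scaffold never observed in the study
#: (precursor numbering): Thr19-Lys20, Leu29, Arg63, Gly220-Lys224.
VDAC1_UNCOVERED = ((19, 20), (29, 29), (63, 63), (220, 224))

#: The seven deamidation sites: (residue letter, precursor position).
VDAC1_DEAMIDATION_SITES = (
    ("N", 37), ("N", 106), ("Q", 166), ("N", 207),
    ("N", 214), ("Q", 226), ("N", 239),
)

#: Position of the fixed-carbamidomethylated reference cysteine.
VDAC1_CYS232 = 232


def _data_path(name: str):
    return resources.files("ptmquant.data").joinpath(name)


def load_vdac_proteins() -> list:
    """The synthetic VDAC1/2/3-like paralog entries."""
    with resources.as_file(_data_path("vdac_synthetic.fasta")) as path:
        return read_fasta(path)


def load_vdac1() -> ProteinEntry:
    return next(p for p in load_vdac_proteins() if p.accession == "VDAC1_SYN")


def coverage_peptide_set(protein: ProteinEntry = None) -> list:
    """A peptide set reproducing the study's coverage pattern on the scaffold.

    Chunks of the covered mature range, leaving uncovered exactly the runs in
    :data:`VDAC1_UNCOVERED`.
    """
    protein = protein or load_vdac1()
    uncovered = set()
    for s, e in VDAC1_UNCOVERED:
        uncovered.update(range(s, e + 1))
    covered_positions = [
        p
        for p in range(VDAC1_MATURE_OFFSET, VDAC1_PRECURSOR_LENGTH + 1)
        if p not in uncovered
    ]
    segments = merge_intervals((p, p) for p in covered_positions)
    peptides = []
    for s, e in segments:
        cursor = s
        while cursor <= e:
            stop = min(cursor + 24, e)
            peptides.append(protein.sequence[cursor - 1 : stop])
            cursor = stop + 1
    return peptides


def load_sulfur_pairs() -> pd.DataFrame:
    """Published per-replicate intensities of the Cys127/Met155 form pairs."""
    with resources.as_file(_data_path("g93a_sulfur_pairs.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_deamidation_pairs() -> pd.DataFrame:
    """Published intensities of the eight deamidated/unmodified peptide pairs."""
    with resources.as_file(_data_path("g93a_deamidation_pairs.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_lfq_means() -> pd.DataFrame:
    """Published per-cell-line mean LFQ intensities of the VDAC paralogs."""
    with resources.as_file(_data_path("lfq_vdac_means.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def example_sim_config_path():
    """Path to the packaged example simulation configuration."""
    return _data_path("example_sim_config.yaml")


def sulfur_pair_forms(row) -> tuple:
    """Build the (modified, reference) :class:`PeptideForm` pair of one
    sulfur-pairs row; the cysteine reference is carbamidomethylated."""
    site = (row["site_residue"], int(row["site_pos"]))
    mod_comp = ((row["modification"], site[1]),)
    ref_comp = ()
    if row["modification"] == "trioxidation":
        ref_comp = (("carbamidomethyl", site[1]),)
    replicate = row["replicate"]
    modified = PeptideForm(
        base_sequence=row["sequence"],
        mod_composition=mod_comp,
        charge=int(row["charge_mod"]),
        start=int(row["start"]),
        measured_mz=float(row["mz_mod"]),
        intensity_by_replicate={replicate: float(row["intensity_mod"])},
    )
    reference = PeptideForm(
        base_sequence=row["sequence"],
        mod_composition=ref_comp,
        charge=int(row["charge_ref"]),
        start=int(row["start"]),
        measured_mz=float(row["mz_ref"]),
        intensity_by_replicate={replicate: float(row["intensity_ref"])},
    )
    return modified, reference


def deamidation_pair_forms(row) -> tuple:
    """Build the (deamidated, unmodified) form pair of one deamidation row;
    peptides spanning Cys232 carry fixed carbamidomethyl on both forms."""
    start, end = int(row["start"]), int(row["end"])
    fixed = (
        (("carbamidomethyl", VDAC1_CYS232),)
        if start <= VDAC1_CYS232 <= end
        else ()
    )
    deamidated = PeptideForm(
        base_sequence=row["sequence"],
        mod_composition=(("deamidation", int(row["site_pos"])),) + fixed,
        charge=int(row["charge_deam"]),
        start=start,
        measured_mz=float(row["mz_deam"]),
        intensity_by_replicate={"I": float(row["intensity_deam"])},
    )
    unmodified = PeptideForm(
        base_sequence=row["sequence"],
        mod_composition=fixed,
        charge=int(row["charge_norm"]),
        start=start,
        measured_mz=float(row["mz_norm"]),
        intensity_by_replicate={"I": float(row["intensity_norm"])},
    )
    return deamidated, unmodified
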