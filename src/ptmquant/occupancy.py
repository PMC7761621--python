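"""Site occupancy ratios from precursor intensities.

The modified-to-reference intensity ratio of a residue's peptide forms is a
rough estimate of modification stoichiometry at that site: the intensity of
the molecular ion carrying the modification divided by the intensity of the
reference (unmodified, or fixed-carbamidomethylated for cysteines) form of
the same base peptide in the same replicate.  Forms observed at different
charge states may be compared directly; such cross-charge pairs are flagged
but not rejected, since ionisation differences are part of the stated
roughness of the estimate.

Display conventions follow the field's reporting habits: ratios >= 1 are
shown with one decimal, ratios < 1 with one significant figure, and replicate
means are shown as integers once they reach 10.  Replicate means are taken
over the display-rounded per-replicate ratios, matching how such tables are
assembled from their printed cells; full precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import AmbiguousPairError, DataError, NoPairError, UndefinedRatioError

#: A site on a protein: residue letter and 1-based position in precursor
#: numbering (the accession is implicit in the form collection).
Site = tuple


@dataclass(frozen=True)
class PeptideForm:
    """A (base sequence, modification composition, charge) precursor species.

    ``mod_composition`` holds ``(modification name, position)`` pairs with
    positions in *protein* (precursor) numbering; ``start`` is the protein
    position of the first peptide residue, so the residue of a modification
    at protein position ``p`` is ``base_sequence[p - start]``.
    ``intensity_by_replicate`` maps a replicate label to the absolute
    intensity of this molecular ion in that run.
    """

    base_sequence: str
    mod_composition: tuple = ()
    charge: int = 2
    start: int = 1
    measured_mz: Optional[float] = None
    intensity_by_replicate: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.charge < 1:
            raise DataError(f"charge must be >= 1, got {self.charge}")
        end = self.start + len(self.base_sequence) - 1
        for name, pos in self.mod_composition:
            if not self.start <= pos <= end:
                raise DataError(
                    f"modification {name!r} at {pos} outside the peptide span "
                    f"{self.start}-{end}"
                )
        for intensity in self.intensity_by_replicate.values():
            if intensity is not None and not intensity >= 0:
                raise DataError(f"negative intensity {intensity}")

    @property
    def end(self) -> int:
        return self.start + len(self.base_sequence) - 1

    def has_modification_at(self, name: str, position: int) -> bool:
        return (name, position) in set(self.mod_composition)

    def total_intensity(self) -> float:
        return sum(v for v in self.intensity_by_replicate.values() if v is not None)


class FormPair(NamedTuple):
    """A modified/reference pair of peptide forms for one site."""

    modified: PeptideForm
    reference: PeptideForm
    cross_charge: bool


@dataclass(frozen=True)
class OccupancyResult:
    """Per-replicate and mean modified/reference intensity ratios for a site."""

    site: tuple  # (accession, residue letter, position)
    modification: str
    ratios: dict  # replicate label -> full-precision ratio
    cross_charge: bool

    @property
    def mean(self) -> float:
        """Full-precision arithmetic mean of the per-replicate ratios."""
        return replicate_mean_ratio(list(self.ratios.values()))

    @property
    def display_mean(self) -> float:
        """Mean of the display-rounded per-replicate ratios (reporting scale)."""
        return replicate_mean_ratio([round_ratio(r) for r in self.ratios.values()])


def _pick(candidates: Sequence[PeptideForm], role: str, site, modification: str,
          tie_break: Optional[str]) -> PeptideForm:
    if not candidates:
        raise NoPairError(
            f"no {role} form for {modification!r} at site {site}"
        )
    if len(candidates) == 1:
        return candidates[0]
    if tie_break == "intensity":
        return max(candidates, key=lambda f: f.total_intensity())
    raise AmbiguousPairError(
        f"{len(candidates)} candidate {role} forms for {modification!r} at "
        f"site {site} and no tie-break"
    )


def pair_forms(
    forms: Iterable[PeptideForm],
    site: Site,
    modification: str,
    tie_break: Optional[str] = "intensity",
) -> FormPair:
    """Select the modified and reference form for a site from a form list.

    All forms must share the same base sequence and span (missed-cleavage
    variants covering the same site are separate evidence and must be paired
    in separate calls).  The modified form carries ``modification`` at the
    site; the reference form does not — other modifications elsewhere (e.g.
    fixed carbamidomethylation) do not disqualify a reference.  With several
    candidates per role the most intense one wins under the default
    tie-break; ``tie_break=None`` raises instead.
    """
    forms = list(forms)
    if not forms:
        raise NoPairError("empty form list")
    base = {(f.base_sequence, f.start) for f in forms}
    if len(base) > 1:
        raise DataError(
            "forms must share one base sequence and span; got "
            + ", ".join(f"{s!r}@{p}" for s, p in sorted(base))
        )
    residue_letter, position = site[-2], site[-1]
    form0 = forms[0]
    if not form0.start <= position <= form0.end:
        raise NoPairError(
            f"site position {position} not covered by span "
            f"{form0.start}-{form0.end}"
        )
    actual = form0.base_sequence[position - form0.start]
    if actual != residue_letter:
        raise DataError(
            f"site expects residue {residue_letter!r} at {position} but the "
            f"peptide has {actual!r}"
        )
    modified = [f for f in forms if f.has_modification_at(modification, position)]
    reference = [f for f in forms if not f.has_modification_at(modification, position)]
    chosen_mod = _pick(modified, "modified", site, modification, tie_break)
    chosen_ref = _pick(reference, "reference", site, modification, tie_break)
    return FormPair(chosen_mod, chosen_ref, chosen_mod.charge != chosen_ref.charge)


def occupancy_ratio(modified_intensity: float, reference_intensity: float) -> float:
    """Modified/reference intensity ratio; undefined for non-positive reference."""
    if not reference_intensity > 0:
        raise UndefinedRatioError(
            f"reference intensity must be positive, got {reference_intensity}"
        )
    if modified_intensity < 0:
        raise DataError(f"negative modified intensity {modified_intensity}")
    return modified_intensity / reference_intensity


def ratios_by_replicate(pair: FormPair) -> dict:
    """Per-replicate ratios over replicates where both forms have intensity."""
    out = {}
    for label, mod_int in pair.modified.intensity_by_replicate.items():
        ref_int = pair.reference.intensity_by_replicate.get(label)
        if mod_int is None or ref_int is None:
            continue
        out[label] = occupancy_ratio(mod_int, ref_int)
    if not out:
        raise NoPairError("no replicate has intensity for both forms")
    return out


def replicate_mean_ratio(ratios: Sequence[float]) -> float:
    """Arithmetic mean of per-replicate ratios."""
    ratios = list(ratios)
    if not ratios:
        raise DataError("cannot average an empty list of ratios")
    return sum(ratios) / len(ratios)


def site_occupancy(
    forms: Iterable[PeptideForm],
    site: tuple,
    modification: str,
    tie_break: Optional[str] = "intensity",
) -> OccupancyResult:
    """Full chain for one site: pair forms, compute per-replicate ratios."""
    pair = pair_forms(forms, site, modification, tie_break)
    return OccupancyResult(
        site=site,
        modification=modification,
        ratios=ratios_by_replicate(pair),
        cross_charge=pair.cross_charge,
    )


# ---------------------------------------------------------------------------
# Display rounding
# ---------------------------------------------------------------------------

def round_ratio(ratio: float) -> float:
    """Display rounding: 1 decimal for ratios >= 1, 1 significant figure below."""
    if ratio < 0:
        raise DataError(f"negative ratio {ratio}")
    if ratio == 0:
        return 0.0
    if ratio >= 1:
        return round(ratio, 1)
    digits = -int(math.floor(math.log10(ratio)))
    return round(ratio, digits)


def format_ratio(ratio: float) -> str:
    value = round_ratio(ratio)
    if ratio >= 1:
        return f"{value:.1f}"
    digits = -int(math.floor(math.log10(value))) if value else 1
    return f"{value:.{digits}f}"


def format_mean_ratio(mean: float) -> str:
    """Replicate means print as integers from 10 up, with 1 decimal below."""
    return f"{round(mean):d}" if mean >= 10 else f"{round(mean, 1):.1f}"
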