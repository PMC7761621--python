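"""Peptide mass and m/z arithmetic.

Monoisotopic peptide mass is the sum of residue masses plus one water; a
modification adds its registered delta.  Charged species m/z uses the bare
proton as charge carrier:  mz = (M + z * m_p) / z.  Observed-vs-theoretical
agreement is expressed in parts per million.
"""

from __future__ import annotations

from typing import Iterable, Union

from .constants import MONOISOTOPIC_RESIDUE_MASSES, PROTON_MASS, WATER_MONOISOTOPIC
from .errors import ConfigurationError, DataError
from .modifications import ANYWHERE, ModificationSpec

#: A modification application: either a bare spec (site left implicit) or a
#: (spec, one-based position) pair, position 0 meaning the N-terminus.
ModApplication = Union[ModificationSpec, tuple]


def monoisotopic_mass(sequence: str, mods: Iterable[ModApplication] = ()) -> float:
    """Monoisotopic mass (Da) of a peptide with optional modifications.

    Parameters
    ----------
    sequence
        Uppercase amino-acid string (20 canonical letters).
    mods
        Modification applications.  A bare :class:`ModificationSpec` is only
        checked for having *some* eligible residue in the peptide; a
        ``(spec, position)`` pair is checked against the residue at that
        one-based position (0 addresses the N-terminus).
    """
    if not sequence:
        raise DataError("cannot compute the mass of an empty sequence")
    try:
        mass = sum(MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in sequence)
    except KeyError as exc:
        raise DataError(f"unknown residue letter {exc.args[0]!r}") from None
    mass += WATER_MONOISOTOPIC
    for application in mods:
        if isinstance(application, ModificationSpec):
            spec, position = application, None
        else:
            spec, position = application
        if position is None:
            if spec.placement == ANYWHERE and not any(
                spec.targets_residue(aa) for aa in sequence
            ):
                raise DataError(
                    f"modification {spec.name!r} targets none of the residues "
                    f"in {sequence!r}"
                )
        elif position == 0:
            if spec.placement == ANYWHERE:
                raise DataError(
                    f"modification {spec.name!r} is not a terminal modification"
                )
        else:
            if not 1 <= position <= len(sequence):
                raise DataError(
                    f"modification position {position} outside 1..{len(sequence)}"
                )
            residue = sequence[position - 1]
            if not spec.targets_residue(residue):
                raise DataError(
                    f"modification {spec.name!r} does not target residue "
                    f"{residue!r} at position {position}"
                )
        mass += spec.delta_mass
    return mass


def theoretical_mz(mass: float, charge: int) -> float:
    """m/z (Th) of a peptide of the given neutral mass at the given charge."""
    if charge < 1:
        raise ConfigurationError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def peptide_mz(
    sequence: str, charge: int, mods: Iterable[ModApplication] = ()
) -> float:
    """Convenience: theoretical m/z of a (possibly modified) peptide."""
    return theoretical_mz(monoisotopic_mass(sequence, mods), charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error of observed vs theoretical m/z, in ppm."""
    if theoretical <= 0:
        raise DataError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def within_tolerance(observed: float, theoretical: float, ppm: float = 10.0) -> bool:
    """Match predicate: |ppm error| <= tolerance (default 10 ppm)."""
    return abs(ppm_error(observed, theoretical)) <= ppm
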