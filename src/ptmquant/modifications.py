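"""Modification registry.

A :class:`ModificationSpec` names a post-translational modification, the
residues it may sit on, its monoisotopic mass delta and its placement rule.
The :class:`ModificationRegistry` resolves the inline tokens found in
"Modified sequence" strings — both short MaxQuant-style abbreviations like
``(de)``, long names like ``(Deamidation (NQ))`` and numeric deltas like
``[+0.98402]`` — to a single canonical spec.

The default registry ships the search-space used for the VDAC1 study:
deamidation of N/Q, the Met and Cys oxidation states, carbamidomethylation,
phosphorylation, succination, the two ubiquitin remnant adducts on Lys,
N-terminal pyroglutamate formation and protein N-terminal acetylation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .errors import ConfigurationError

#: Placement rules.
ANYWHERE = "anywhere"
PEPTIDE_NTERM = "peptide_nterm"
PROTEIN_NTERM = "protein_nterm"

_PLACEMENTS = (ANYWHERE, PEPTIDE_NTERM, PROTEIN_NTERM)


@dataclass(frozen=True)
class ModificationSpec:
    """A named modification with residue targets and a monoisotopic delta.

    ``targets`` holds residue letters; the wildcard ``"*"`` (used by terminal
    modifications such as protein N-terminal acetylation) accepts any residue.
    """

    name: str
    targets: frozenset
    delta_mass: float
    placement: str = ANYWHERE
    aliases: tuple = field(default=())

    def __post_init__(self):
        if not self.targets:
            raise ConfigurationError(f"modification {self.name!r} has no targets")
        if self.placement not in _PLACEMENTS:
            raise ConfigurationError(
                f"modification {self.name!r}: unknown placement {self.placement!r}"
            )

    def targets_residue(self, residue: str) -> bool:
        return "*" in self.targets or residue in self.targets


def _spec(name, targets, delta, placement=ANYWHERE, aliases=()):
    return ModificationSpec(name, frozenset(targets), delta, placement, tuple(aliases))


#: The default modification set (deltas in Da).  The two ubiquitin remnant
#: adducts use the deltas exactly as reported for the search (GG +114.0429,
#: LRGG +383.2281) rather than recomputed compositions.
DEFAULT_MODIFICATIONS = (
    _spec("deamidation", "NQ", 0.98402, aliases=("de", "deam", "deamidated")),
    _spec("oxidation", "M", 15.99491, aliases=("ox",)),
    _spec("dioxidation", "MC", 31.98983, aliases=("2ox", "sulfone")),
    _spec("trioxidation", "C", 47.98474, aliases=("3ox", "sulfonic-acid")),
    _spec(
        "carbamidomethyl",
        "C",
        57.02146,
        aliases=("cam", "carbamidomethylation", "carboxyamidomethyl"),
    ),
    _spec("phospho", "STY", 79.96633, aliases=("ph", "phosphorylation")),
    _spec("acetyl", "*", 42.01057, placement=PROTEIN_NTERM, aliases=("ac",)),
    _spec("pyro-glu-q", "Q", -17.02655, placement=PEPTIDE_NTERM,
          aliases=("gln->pyro-glu", "pyroglutamate-q")),
    _spec("pyro-glu-e", "E", -18.01056, placement=PEPTIDE_NTERM,
          aliases=("glu->pyro-glu", "pyroglutamate-e")),
    _spec("succination", "C", 116.01096, aliases=("2sc", "succinated")),
    _spec("gg", "K", 114.0429, aliases=("glygly", "ubiquitin-remnant")),
    _spec("lrgg", "K", 383.2281, aliases=("leuarg-glygly",)),
)


class ModificationRegistry:
    """Lookup of modification specs by name, alias, inline token or delta."""

    def __init__(self, specs: Iterable[ModificationSpec] = DEFAULT_MODIFICATIONS):
        self._by_name: dict[str, ModificationSpec] = {}
        self._by_alias: dict[str, ModificationSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: ModificationSpec) -> None:
        key = spec.name.lower()
        if key in self._by_name:
            raise ConfigurationError(f"duplicate modification name {spec.name!r}")
        self._by_name[key] = spec
        for alias in (spec.name, *spec.aliases):
            self._by_alias[alias.lower()] = spec

    def __iter__(self):
        return iter(self._by_name.values())

    def __contains__(self, name) -> bool:
        return name.lower() in self._by_name

    def get(self, name: str) -> ModificationSpec:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise ConfigurationError(f"unknown modification {name!r}") from None

    def resolve_token(self, token: str) -> ModificationSpec:
        """Resolve an inline token such as ``de`` or ``Deamidation (NQ)``."""
        key = token.strip().lower()
        if key in self._by_alias:
            return self._by_alias[key]
        # MaxQuant long form: "<Name> (<targets>)" — retry on the head word(s).
        head = re.sub(r"\s*\([^()]*\)\s*$", "", key)
        if head != key and head in self._by_alias:
            return self._by_alias[head]
        raise ConfigurationError(
            f"modification token {token!r} not found in the registry"
        )

    def resolve_delta(self, delta: float, tol: float = 0.01) -> ModificationSpec:
        """Resolve a numeric token like ``[+0.98402]`` by nearest mass delta."""
        best, best_err = None, tol
        for spec in self:
            err = abs(spec.delta_mass - delta)
            if err <= best_err:
                best, best_err = spec, err
        if best is None:
            raise ConfigurationError(
                f"no registered modification within {tol} Da of delta {delta:+.5f}"
            )
        return best

    @classmethod
    def from_yaml(cls, path) -> "ModificationRegistry":
        """Load a registry from a human-editable YAML file.

        Layout: a mapping of name -> {targets: "NQ", delta_mass: 0.98402,
        placement: anywhere, aliases: [de]}.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping of modifications")
        specs = []
        for name, entry in raw.items():
            try:
                specs.append(
                    _spec(
                        name,
                        entry["targets"],
                        float(entry["delta_mass"]),
                        entry.get("placement", ANYWHERE),
                        tuple(entry.get("aliases", ())),
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"{path}: modification {name!r} is missing key {exc}"
                ) from None
        return cls(specs)


def default_registry() -> ModificationRegistry:
    """A fresh registry with the default modification set."""
    return ModificationRegistry(DEFAULT_MODIFICATIONS)
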