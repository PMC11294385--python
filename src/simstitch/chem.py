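"""Chemical building blocks and copper-bound diastereomeric cluster ions.

Enantiomers have identical collision cross sections, so chiral analysis by ion
mobility proceeds indirectly: the analyte amino acid is assembled, in the
electrospray plume, into non-covalent copper complexes together with chiral
selector amino acids (here L-Phe and L-Pro).  The resulting ``[M−H+Cu(II)]⁺``
dimer and trimer cluster ions are diastereomers of one another when the
analyte handedness differs, and diastereomers *can* differ in mobility.

This module defines :class:`Molecule` (an analyte or selector with a known
elemental composition), enumerates the dimer/trimer stoichiometries screened
per analyte, and computes exact m/z values for the singly charged copper
adducts, including the electron-mass correction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, DomainError

__all__ = [
    "ELEMENT_MASS",
    "ISOTOPE_MASS",
    "ELECTRON_MASS",
    "PROTON_COMPANION_MASS",
    "AMINO_ACID_FORMULAS",
    "Molecule",
    "ComplexSpec",
    "PanelConfig",
    "formula_mass",
    "parse_formula",
    "builtin_molecule",
    "load_panel",
    "load_building_blocks",
    "make_complex",
    "complex_mz",
    "enumerate_complexes",
    "parse_label",
    "apply_cystine_rule",
]

# NIST monoisotopic atomic masses, Da (most abundant isotope).
ELEMENT_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# Specific isotopes selectable for the metal centre.
ISOTOPE_MASS: Mapping[tuple[str, int], float] = {
    ("Cu", 63): 62.92959772,
    ("Cu", 65): 64.92789527,
}

ELECTRON_MASS = 5.48579909e-4  # Da
PROTON_COMPANION_MASS = ELEMENT_MASS["H"]  # neutral H lost on deprotonation

# Free (non-residue) monoisotopic formulas of the 19 chiral proteinogenic
# amino acids handled by the screen (glycine is achiral and excluded).
AMINO_ACID_FORMULAS: Mapping[str, str] = {
    "Ala": "C3H7NO2",
    "Arg": "C6H14N4O2",
    "Asn": "C4H8N2O3",
    "Asp": "C4H7NO4",
    "Cys": "C3H7NO2S",
    "Gln": "C5H10N2O3",
    "Glu": "C5H9NO4",
    "His": "C6H9N3O2",
    "Ile": "C6H13NO2",
    "Leu": "C6H13NO2",
    "Lys": "C6H14N2O2",
    "Met": "C5H11NO2S",
    "Phe": "C9H11NO2",
    "Pro": "C5H9NO2",
    "Ser": "C3H7NO3",
    "Thr": "C4H9NO3",
    "Trp": "C11H12N2O2",
    "Tyr": "C9H11NO3",
    "Val": "C5H11NO2",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHIRALITIES = ("L", "D", "achiral", "unspecified")
_ROLES = ("analyte", "selector")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C5H9NO2"`` (or pass through a mapping) into element counts."""
    if isinstance(formula, Mapping):
        return {el: int(n) for el, n in formula.items()}
    counts: dict[str, int] = {}
    consumed = 0
    for el, n in _FORMULA_RE.findall(formula):
        if not el:
            continue
        consumed += len(el) + len(n)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    if consumed != len(formula):
        raise ConfigurationError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral formula from the element table."""
    counts = parse_formula(formula)
    try:
        return sum(ELEMENT_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise ConfigurationError(f"no monoisotopic mass for element {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class Molecule:
    """A neutral building block of a cluster ion (analyte or chiral selector).

    ``monoisotopic_mass`` is the neutral monoisotopic mass in Da.  When a
    formula is supplied the mass must agree with the element table within
    1e-4 Da, which guards against typos in custom panel entries.
    """

    name: str
    monoisotopic_mass: float
    formula: tuple[tuple[str, int], ...] | None = None
    chirality: str = "unspecified"
    role: str = "analyte"

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise DomainError(f"{self.name}: monoisotopic mass must be > 0")
        if self.chirality not in _CHIRALITIES:
            raise DomainError(f"{self.name}: bad chirality {self.chirality!r}")
        if self.role not in _ROLES:
            raise DomainError(f"{self.name}: bad role {self.role!r}")
        if self.formula is not None:
            fdict = dict(self.formula)
            computed = formula_mass(fdict)
            if abs(computed - self.monoisotopic_mass) > 1e-4:
                raise DomainError(
                    f"{self.name}: mass {self.monoisotopic_mass:.5f} disagrees with "
                    f"formula mass {computed:.5f} by more than 1e-4 Da"
                )

    @property
    def formula_dict(self) -> dict[str, int] | None:
        return dict(self.formula) if self.formula is not None else None


def _freeze_formula(formula: str | Mapping[str, int] | None):
    if formula is None:
        return None
    counts = parse_formula(formula)
    return tuple(sorted(counts.items()))


def molecule(name: str, formula: str | Mapping[str, int] | None = None,
             mass: float | None = None, chirality: str = "unspecified",
             role: str = "analyte") -> Molecule:
    """Build a :class:`Molecule` from a formula and/or an explicit mass."""
    frozen = _freeze_formula(formula)
    if mass is None:
        if frozen is None:
            raise ConfigurationError(f"molecule {name!r} needs a formula or a mass")
        mass = formula_mass(dict(frozen))
    return Molecule(name=name, monoisotopic_mass=mass, formula=frozen,
                    chirality=chirality, role=role)


def builtin_molecule(name: str, chirality: str = "unspecified",
                     role: str = "analyte") -> Molecule:
    """Resolve one of the 19 built-in chiral amino acids by three-letter code."""
    try:
        formula = AMINO_ACID_FORMULAS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown molecule {name!r}: not in the built-in amino-acid table "
            f"and no formula/mass given"
        ) from None
    return molecule(name, formula=formula, chirality=chirality, role=role)


@dataclass(frozen=True)
class PanelConfig:
    """A resolved screening panel: analytes, chiral selectors, metal centre."""

    analytes: tuple[Molecule, ...]
    selectors: tuple[Molecule, ...]
    metal: tuple[str, int] = ("Cu", 63)


def load_panel(config: str | Path | Mapping) -> PanelConfig:
    """Load and resolve a panel definition (YAML/JSON path or parsed mapping).

    Keys: ``analytes`` (names), ``selectors`` (names), optional ``metal``
    ({element, isotope}) and ``custom_molecules`` ([{name, formula|mass}]).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if config is None:
        config = {}
    custom: dict[str, Molecule] = {}
    for entry in config.get("custom_molecules", []) or []:
        name = entry.get("name")
        if not name:
            raise ConfigurationError("custom molecule entry without a name")
        custom[name] = molecule(name, formula=entry.get("formula"),
                                mass=entry.get("mass"),
                                chirality=entry.get("chirality", "unspecified"))

    def resolve(name: str, role: str) -> Molecule:
        if name in custom:
            return replace(custom[name], role=role)
        return builtin_molecule(name, role=role)

    analytes = tuple(resolve(n, "analyte") for n in config.get("analytes", []) or [])
    selectors = tuple(resolve(n, "selector") for n in config.get("selectors", []) or [])
    metal_cfg = config.get("metal") or {}
    metal = (metal_cfg.get("element", "Cu"), int(metal_cfg.get("isotope", 63)))
    if metal not in ISOTOPE_MASS:
        raise ConfigurationError(f"no isotope mass for metal {metal}")
    return PanelConfig(analytes=analytes, selectors=selectors, metal=metal)


def load_building_blocks(config: str | Path | Mapping) -> list[Molecule]:
    """Resolve every molecule named by a panel config (analytes then selectors)."""
    panel = load_panel(config)
    return list(panel.analytes) + list(panel.selectors)


@dataclass(frozen=True)
class ComplexSpec:
    """A singly charged copper-bound cluster ion ``[Σcomponents − H + Cu]⁺``.

    ``components`` is an ordered multiset of 1–3 neutral molecules (one
    component only occurs for covalent-dimer substitutions such as cystine).
    """

    components: tuple[Molecule, ...]
    metal: tuple[str, int] = ("Cu", 63)
    proton_delta: int = -1
    charge: int = 1
    label: str = ""
    mz: float = 0.0

    def __post_init__(self):
        if not 1 <= len(self.components) <= 3:
            raise DomainError(
                f"{self.label or 'complex'}: component count {len(self.components)} "
                "outside {1, 2, 3}"
            )
        if self.metal not in ISOTOPE_MASS:
            raise DomainError(f"no isotope mass for metal {self.metal}")
        if self.charge < 1:
            raise DomainError("charge must be a positive integer")
        if self.mz and self.mz <= 0:
            raise DomainError(f"{self.label}: mz must be > 0")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.components)

    @property
    def stoichiometry_key(self) -> tuple[str, ...]:
        """Order-free identity of the cluster (sorted component names)."""
        return tuple(sorted(self.component_names))


def _build_label(names: Sequence[str]) -> str:
    return "[" + "+".join(names) + "-H+Cu(II)]+"


def complex_mz(spec: ComplexSpec) -> float:
    """Exact m/z of the cluster cation.

    ``mz = (Σ m(component) + proton_delta·m(H) + m(metal isotope)
    − charge·m(e)) / charge``.  The electron-mass subtraction matters at the
    ±0.01 Da extraction tolerance used downstream.
    """
    for mol in spec.components:
        if mol.monoisotopic_mass is None or mol.monoisotopic_mass <= 0:
            raise DomainError(f"component {mol.name!r} has no resolved mass")
    total = sum(m.monoisotopic_mass for m in spec.components)
    total += spec.proton_delta * PROTON_COMPANION_MASS
    total += ISOTOPE_MASS[spec.metal]
    total -= spec.charge * ELECTRON_MASS
    mz = total / spec.charge
    if mz <= 0:
        raise DomainError(f"non-physical m/z {mz:.6f} for {spec.label or spec.component_names}")
    return mz


def make_complex(components: Sequence[Molecule],
                 metal: tuple[str, int] = ("Cu", 63),
                 proton_delta: int = -1, charge: int = 1) -> ComplexSpec:
    """Assemble a :class:`ComplexSpec` with its canonical label and exact m/z."""
    comps = tuple(components)
    spec = ComplexSpec(components=comps, metal=metal, proton_delta=proton_delta,
                       charge=charge)
    mz = complex_mz(spec)
    label = _build_label([m.name for m in comps])
    return replace(spec, label=label, mz=mz)


def enumerate_complexes(analytes: Sequence[Molecule],
                        selectors: Sequence[Molecule],
                        metal: tuple[str, int] = ("Cu", 63)) -> list[ComplexSpec]:
    """Enumerate the dimer/trimer cluster stoichiometries screened per analyte.

    For each analyte AA, all size-2 and size-3 multisets over
    ``{AA} ∪ selectors`` containing at least one AA copy are generated.  With
    the two-selector panel {Phe, Pro} this yields exactly the nine cluster
    stoichiometries screened per analyte — dimers AA+Pro, AA+Phe, AA+AA and
    trimers AA+Pro+Pro, AA+Phe+Pro, AA+Phe+Phe, AA+AA+Pro, AA+AA+Phe,
    AA+AA+AA — hence 9n species for n analytes (153 for 17).

    Output is deduplicated by component multiset and ordered canonically:
    dimers before trimers, then lexically by label.
    """
    sorted_selectors = sorted(selectors, key=lambda m: m.name)
    specs: list[ComplexSpec] = []
    seen: set[tuple] = set()
    for analyte in analytes:
        for size in (2, 3):
            for n_analyte in range(size, 0, -1):
                for sel_combo in itertools.combinations_with_replacement(
                        sorted_selectors, size - n_analyte):
                    comps = (analyte,) * n_analyte + sel_combo
                    key = (tuple(sorted(m.name for m in comps)), metal)
                    if key in seen:
                        continue
                    seen.add(key)
                    specs.append(make_complex(comps, metal=metal))
    specs.sort(key=lambda s: (len(s.components), s.label))
    return specs


_LABEL_RE = re.compile(r"^\[(?P<core>.+)-H\+Cu\(II\)\]\+$")


def parse_label(label: str, molecules: Mapping[str, Molecule] | Iterable[Molecule],
                metal: tuple[str, int] = ("Cu", 63)) -> ComplexSpec:
    """Parse a canonical complex label back into an equivalent ComplexSpec.

    Grammar: ``"[" name ("+" name)* "-H+Cu(II)" "]+"``.  Component names are
    resolved against the provided molecule registry.
    """
    match = _LABEL_RE.match(label)
    if match is None:
        raise ConfigurationError(f"label {label!r} does not match the complex grammar")
    if not isinstance(molecules, Mapping):
        molecules = {m.name: m for m in molecules}
    comps = []
    for name in match.group("core").split("+"):
        if name not in molecules:
            raise ConfigurationError(f"label component {name!r} not in molecule registry")
        comps.append(molecules[name])
    return make_complex(comps, metal=metal)


def apply_cystine_rule(spec: ComplexSpec) -> ComplexSpec:
    """Substitute pairs of Cys by the covalent cystine dimer (Cys₂ − 2H).

    Cysteine is screened like any other analyte, but the species actually
    observed is the oxidised covalent dimer: every Cys pair among the
    components is replaced by one ``Cys2`` molecule of mass 2·m(Cys) − 2·m(H).
    Specs without a Cys pair are returned unchanged.
    """
    names = list(spec.component_names)
    if names.count("Cys") < 2:
        return spec
    cys = next(m for m in spec.components if m.name == "Cys")
    cystine = molecule("Cys2", formula="C6H12N2O4S2",
                       mass=2 * cys.monoisotopic_mass - 2 * ELEMENT_MASS["H"],
                       role=cys.role)
    comps: list[Molecule] = []
    pending = 0
    for m in spec.components:
        if m.name == "Cys":
            pending += 1
            if pending == 2:
                comps.append(cystine)
                pending = 0
        else:
            comps.append(m)
    if pending:
        comps.append(cys)
    return make_complex(comps, metal=spec.metal, proton_delta=spec.proton_delta,
                        charge=spec.charge)
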