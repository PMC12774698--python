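"""Elemental-formula arithmetic, monoisotopic masses and lipid sum-composition expansion.

Lipid classes are described by a *generic* formula anchored at zero radyl
carbons and zero radyl double bonds.  A concrete sum-composition species
``CLASS(C:db)`` is obtained by adding ``C`` methylene units (CH2) and removing
one H2 per double bond:

    neutral_formula = base_formula + C * {C:1, H:2} - db * {H:2}

Masses are stored internally as integer micro-Dalton so that formula addition
and mass addition commute exactly; the public API reports float Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "ElementalFormula",
    "IsotopeMassTable",
    "DEFAULT_MASS_TABLE",
    "AdductSpec",
    "LipidClassDefinition",
    "LipidSpecies",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "expand_class",
    "species_name",
    "parse_species_name",
    "default_max_db",
]


class FormulaError(ValueError):
    """Malformed formula text or invalid element arithmetic."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count composition.

    Counts are non-negative integers; the all-zero (empty) formula is valid
    and is the identity for addition.  ``D`` denotes deuterium (2H) and is
    tracked as its own symbol so that labelled internal standards keep their
    mass shift.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not isinstance(n, int):
                raise FormulaError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: {merged[el]}"
                )
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def hill_string(self) -> str:
        """Hill-order text: C first, then H, then the rest alphabetically."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalFormula({self.hill_string() or 'empty'})"


EMPTY_FORMULA = ElementalFormula({})
CH2 = ElementalFormula({"C": 1, "H": 2})
H2 = ElementalFormula({"H": 2})


def parse_formula(text: str) -> ElementalFormula:
    """Parse Hill-style formula text such as ``"C36H72NO8P"``.

    The isotope label ``D`` (deuterium) is accepted as an element symbol.
    An empty string is rejected: the empty formula is only available through
    the explicit constructor.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string; use ElementalFormula({}) explicitly")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in DEFAULT_MASS_TABLE.known_elements:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


class IsotopeMassTable:
    """Monoisotopic masses (most abundant isotope; D = 2H), immutable.

    Masses are held as exact integer micro-Dalton (1e-6 Da).  CODATA/IUPAC
    values rounded to 6 decimals.
    """

    def __init__(self, micro_da: Mapping[str, int], electron_micro_da: int) -> None:
        self._micro = MappingProxyType(dict(micro_da))
        self._electron = electron_micro_da

    @property
    def known_elements(self) -> frozenset:
        return frozenset(self._micro)

    @property
    def electron_mass(self) -> float:
        """Electron mass in Da."""
        return self._electron / 1e6

    def mass_micro(self, f: ElementalFormula) -> int:
        """Exact integer micro-Dalton mass; additive without rounding error."""
        total = 0
        for el, n in f.counts.items():
            try:
                total += n * self._micro[el]
            except KeyError:
                raise FormulaError(f"no mass entry for element {el!r}") from None
        return total

    def mass(self, f: ElementalFormula) -> float:
        return self.mass_micro(f) / 1e6


DEFAULT_MASS_TABLE = IsotopeMassTable(
    {
        "H": 1_007_825,   # 1.007825
        "D": 2_014_102,   # 2.014102 (2H)
        "C": 12_000_000,
        "N": 14_003_074,
        "O": 15_994_915,
        "P": 30_973_762,
        "S": 31_972_071,
        "Na": 22_989_769,
        "K": 38_963_707,
        "Cl": 34_968_853,
    },
    electron_micro_da=549,  # 0.000549
)


def monoisotopic_mass(
    f: ElementalFormula, table: IsotopeMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral monoisotopic mass in Da (sum of count x isotope mass)."""
    return table.mass(f)


@dataclass(frozen=True)
class AdductSpec:
    """Electrospray adduct: m/z = (n_M*M + sign*mass(delta) - z*m_e) / |z|."""

    name: str
    delta_formula: ElementalFormula
    z: int
    sign: int = 1
    n_M: int = 1

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"adduct {self.name!r}: charge must be nonzero")
        if self.sign not in (-1, 1):
            raise ValueError(f"adduct {self.name!r}: sign must be +1 or -1")
        if self.n_M < 1:
            raise ValueError(f"adduct {self.name!r}: n_M must be >= 1")

    @property
    def polarity(self) -> str:
        return "+" if self.z > 0 else "-"


def adduct_mz(
    neutral_mass: float,
    adduct: AdductSpec,
    table: IsotopeMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z (Th) of an adduct ion of a neutral molecule of mass ``neutral_mass``."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    delta = table.mass(adduct.delta_formula) * adduct.sign
    return (adduct.n_M * neutral_mass + delta - adduct.z * table.electron_mass) / abs(
        adduct.z
    )


@dataclass(frozen=True)
class LipidClassDefinition:
    """Generic lipid class: base formula at (0:0) plus enumeration ranges."""

    class_code: str
    base_formula: ElementalFormula
    n_chains: int
    carbon_range: Tuple[int, int]
    db_range: Tuple[int, int]
    adducts_pos: Tuple[str, ...] = ()
    adducts_neg: Tuple[str, ...] = ()
    internal_standard: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_chains > 4:
            raise ValueError(f"{self.class_code}: n_chains must be in 1..4")
        c_lo, c_hi = self.carbon_range
        d_lo, d_hi = self.db_range
        if c_lo < 0 or d_lo < 0:
            raise ValueError(f"{self.class_code}: ranges must be non-negative")
        if not self.adducts_pos and not self.adducts_neg:
            raise ValueError(f"{self.class_code}: at least one adduct required")


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition species CLASS(C:db) with its neutral formula.

    ``name_override`` accommodates molecules named outside the canonical
    scheme, e.g. the deuterated standard "CE(16:0)-d7".
    """

    class_code: str
    total_carbons: int
    total_double_bonds: int
    neutral_formula: ElementalFormula
    neutral_mass: float
    name_override: Optional[str] = None

    @property
    def name(self) -> str:
        if self.name_override is not None:
            return self.name_override
        return species_name(self.class_code, self.total_carbons, self.total_double_bonds)


def species_name(class_code: str, c: int, db: int) -> str:
    return f"{class_code}({c}:{db})"


_SPECIES_NAME = re.compile(r"^(?P<cls>.+)\((?P<c>\d+):(?P<db>\d+)\)$")


def parse_species_name(name: str) -> Tuple[str, int, int]:
    """Invert :func:`species_name`: ``"PC(54:3)" -> ("PC", 54, 3)``."""
    m = _SPECIES_NAME.match(name)
    if not m:
        raise ValueError(f"not a CLASS(C:db) species name: {name!r}")
    return m.group("cls"), int(m.group("c")), int(m.group("db"))


def default_max_db(total_carbons: int, n_chains: int) -> int:
    """Default cap on double bonds: at most one per two radyl carbons."""
    return total_carbons // 2


def expand_class(
    defn: LipidClassDefinition,
    constraint=default_max_db,
    table: IsotopeMassTable = DEFAULT_MASS_TABLE,
) -> List[LipidSpecies]:
    """Enumerate every (C, db) sum composition of a class.

    One species per grid point with ``C`` in ``carbon_range``, ``db`` in
    ``db_range`` and ``db <= constraint(C, n_chains)``; sorted by (C, db).
    Empty ranges yield an empty list.
    """
    c_lo, c_hi = defn.carbon_range
    d_lo, d_hi = defn.db_range
    out: List[LipidSpecies] = []
    for c in range(c_lo, c_hi + 1):
        db_cap = d_hi if constraint is None else min(d_hi, constraint(c, defn.n_chains))
        for db in range(d_lo, db_cap + 1):
            formula = defn.base_formula + c * CH2 - db * H2
            out.append(
                LipidSpecies(
                    class_code=defn.class_code,
                    total_carbons=c,
                    total_double_bonds=db,
                    neutral_formula=formula,
                    neutral_mass=table.mass(formula),
                )
            )
    return out
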