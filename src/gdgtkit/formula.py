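"""Elemental-formula arithmetic for ether-lipid mass spectrometry.

Everything downstream (lipid construction, fragment prediction, feature
annotation) reduces to sums and differences of small elemental formulas and
their monoisotopic masses.  The atomic-mass table is pinned in source so
that the theoretical m/z values this package reports are stable and
independent of any third-party mass compilation; reported cation m/z values
are electron-corrected (a proton weighs 1.00727645 Da, not 1.00782503 Da).

Only singly charged positive adducts are modelled: [M+H]+, [M+NH4]+ and
[M+Na]+, the three most abundant adducts observed for archaeal ether lipids
in positive-mode ESI.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "get_adduct",
    "MassTolerance",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_mz",
]

#: Monoisotopic atomic masses in Da, pinned for reproducibility.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.000000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
}

#: Electron rest mass in Da; subtracted once per (positive) charge.
ELECTRON_MASS: float = 0.00054858

#: Mass of the proton (H+ cation), electron-corrected.
PROTON_MASS: float = ATOMIC_MASS["H"] - ELECTRON_MASS

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Unknown element, malformed formula string, or negative count."""


class ElementalFormula(Mapping[str, int]):
    """Immutable element -> count map with element-wise arithmetic.

    Supports ``+``, ``-`` (negative results raise :class:`FormulaError`)
    and multiplication by a non-negative integer.  Formats to Hill
    notation (C first, H second, remaining elements alphabetical).

    >>> ElementalFormula({"C": 3, "H": 8, "O": 3}) + ElementalFormula({"H": 2, "O": 1})
    ElementalFormula('C3H10O4')
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        if counts:
            for element, n in counts.items():
                if element not in ATOMIC_MASS:
                    raise FormulaError(f"unsupported element: {element!r}")
                n = int(n)
                if n < 0:
                    raise FormulaError(f"negative count for {element}: {n}")
                if n:
                    clean[element] = n
        self._counts: dict[str, int] = dict(sorted(clean.items()))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count: "
                    f"{self.hill()} - {other.hill()}"
                )
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int):
            return NotImplemented
        if k < 0:
            raise FormulaError(f"cannot multiply formula by negative {k}")
        return ElementalFormula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- formatting -------------------------------------------------------
    def hill(self) -> str:
        """Hill-notation string: C, H, then other elements alphabetically."""
        parts = []
        for el in ("C", "H"):
            n = self._counts.get(el, 0)
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(set(self._counts) - {"C", "H"}):
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string, e.g. ``"C86H172O6"``.

    Counts default to 1 when omitted; repeated element symbols accumulate.
    Raises :class:`FormulaError` on unknown elements or malformed input.
    """
    if not isinstance(text, str):
        raise FormulaError(f"expected a formula string, got {type(text).__name__}")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula string: {text!r}")
        element, digits = match.group(1), match.group(2)
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula string: {text!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    if not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive adduct (cationisation) of a neutral lipid."""

    name: str
    cation_formula: ElementalFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged adducts are modelled")

    @property
    def cation_mass(self) -> float:
        """Electron-corrected mass of the attached cation in Da."""
        return monoisotopic_mass(self.cation_formula) - self.charge * ELECTRON_MASS


#: The three supported positive adducts.
ADDUCTS: dict[str, AdductSpec] = {
    "+H": AdductSpec("+H", parse_formula("H")),
    "+NH4": AdductSpec("+NH4", parse_formula("NH4")),
    "+Na": AdductSpec("+Na", parse_formula("Na")),
}


def get_adduct(adduct: Union[str, AdductSpec]) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(neutral: ElementalFormula, adduct: Union[str, AdductSpec]) -> float:
    """m/z of the singly charged adduct ion of a neutral formula.

    Full double precision; use :func:`round_mz` when reporting values,
    which matches the 3-decimal convention of high-resolution instruments.
    """
    spec = get_adduct(adduct)
    return monoisotopic_mass(neutral) + spec.cation_mass


def round_mz(mz: float, ndigits: int = 3) -> float:
    """Round an m/z for reporting (round-half-even, 3 decimals by default)."""
    return round(mz, ndigits)


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MassTolerance:
    """A mass-matching tolerance, either relative (ppm) or absolute (Da)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'Da', got {self.unit!r}")
        if self.value <= 0:
            raise ValueError(f"tolerance must be positive, got {self.value}")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window in Da at a given m/z."""
        return self.value * 1e-6 * mz if self.unit == "ppm" else self.value

    def matches(self, observed: float, theoretical: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)
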