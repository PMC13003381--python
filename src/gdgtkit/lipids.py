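"""Constructive structural model of archaeal ether lipids.

Archaeal membrane lipids are built from glycerol units carrying
ether-bound, fully saturated isoprenoid chains:

* **AR** (archaeol): one glycerol with two pendant chains (C20 phytanyl or
  C25 sesterterpanyl) — a bilayer-forming diether.
* **GDGT**: two glycerols bridged by two membrane-spanning chains (C40
  biphytanyl, or the extended C45 nonaprenyl / C50 decaprenyl variants).
* **GTGT**: two glycerols joined by a single bridging chain plus two
  pendant chains — the trialkyl intermediate of GDGT biosynthesis, two
  hydrogens heavier than the corresponding GDGT.
* **GMGT**: a GDGT whose bridging chains are additionally joined by a
  covalent C-C bond (one H2 lighter than the GDGT).

Bridging chains may carry cyclopentane rings (each ring -H2) and the polar
head is zero to three glycosidically bound hexoses (each +C6H10O5).
Formulas are derived by condensation: component alcohols/diols plus
glycerols minus one water per ether bond formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

from .formula import (
    ElementalFormula,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "PENDANT_CARBONS",
    "BRIDGING_CARBONS",
    "CORES",
    "ChainSpec",
    "LipidDescriptor",
    "LibraryEntry",
    "build_formula",
    "systematic_name",
    "canonical_descriptor",
    "enumerate_library",
    "default_library",
    "library_frame",
    "write_library",
    "find_entry",
]

PENDANT_CARBONS = (20, 25)
BRIDGING_CARBONS = (40, 45, 50)
CORES = ("AR", "GDGT", "GTGT", "GMGT")

#: Expected chain roles per core type: (n_pendant, n_bridging).
_CORE_CHAINS = {"AR": (2, 0), "GDGT": (0, 2), "GTGT": (2, 1), "GMGT": (0, 2)}

#: Ether bonds formed on condensation (one H2O each).
_ETHER_BONDS = {"AR": 2, "GDGT": 4, "GTGT": 4, "GMGT": 4}

_GLYCEROLS = {"AR": 1, "GDGT": 2, "GTGT": 2, "GMGT": 2}

GLYCEROL = parse_formula("C3H8O3")
HEXOSE_UNIT = parse_formula("C6H10O5")  # hexose residue after glycosidic bond
WATER = parse_formula("H2O")
H2 = parse_formula("H2")
ISOPRENOID_UNIT = parse_formula("C5H10")

_CORE_TOKEN = {"AR": "AR", "GDGT": "iGDGT", "GTGT": "iGTGT", "GMGT": "GMGT"}
_EXT_PREFIX = {0: "", 1: "ext-", 2: "di-ext-"}

MAX_RINGS = 8


@dataclass(frozen=True)
class ChainSpec:
    """One isoprenoid chain: carbon number, role, and cyclopentane rings."""

    carbons: int
    role: str  # "pendant" | "bridging"
    rings: int = 0

    def __post_init__(self) -> None:
        if self.role == "pendant":
            if self.carbons not in PENDANT_CARBONS:
                raise ValueError(
                    f"pendant chains must have {PENDANT_CARBONS} carbons, "
                    f"got C{self.carbons}"
                )
            if self.rings:
                raise ValueError("cyclopentane rings are only allowed on bridging chains")
        elif self.role == "bridging":
            if self.carbons not in BRIDGING_CARBONS:
                raise ValueError(
                    f"bridging chains must have {BRIDGING_CARBONS} carbons, "
                    f"got C{self.carbons}"
                )
            if not 0 <= self.rings <= MAX_RINGS:
                raise ValueError(f"rings must be within 0..{MAX_RINGS}, got {self.rings}")
        else:
            raise ValueError(f"chain role must be 'pendant' or 'bridging', got {self.role!r}")

    @property
    def extensions(self) -> int:
        """Number of extra C5 isoprenoid units relative to the regular chain."""
        base = 20 if self.role == "pendant" else 40
        return (self.carbons - base) // 5

    def formula(self) -> ElementalFormula:
        """The chain as its free saturated alcohol (pendant) or diol (bridging)."""
        n = self.carbons
        oxygens = 1 if self.role == "pendant" else 2
        return ElementalFormula({"C": n, "H": 2 * n + 2, "O": oxygens}) - self.rings * H2


@dataclass(frozen=True)
class LipidDescriptor:
    """Structural recipe of an archaeal ether lipid.

    The elemental formula and the systematic name are both derived
    deterministically from these fields alone.
    """

    core: str
    chains: tuple[ChainSpec, ...]
    hexoses: int = 0

    def __post_init__(self) -> None:
        if self.core not in CORES:
            raise ValueError(f"core must be one of {CORES}, got {self.core!r}")
        object.__setattr__(self, "chains", tuple(self.chains))
        n_pendant = sum(1 for c in self.chains if c.role == "pendant")
        n_bridging = sum(1 for c in self.chains if c.role == "bridging")
        if (n_pendant, n_bridging) != _CORE_CHAINS[self.core]:
            raise ValueError(
                f"{self.core} requires {_CORE_CHAINS[self.core]} (pendant, bridging) "
                f"chains, got ({n_pendant}, {n_bridging})"
            )
        if not 0 <= self.hexoses <= 3:
            raise ValueError(f"hexose count must be within 0..3, got {self.hexoses}")
        if self.total_rings > MAX_RINGS:
            raise ValueError(f"total ring count exceeds {MAX_RINGS}")

    @property
    def total_rings(self) -> int:
        return sum(c.rings for c in self.chains)

    @property
    def extensions(self) -> int:
        """Total number of extra isoprenoid units across all chains."""
        return sum(c.extensions for c in self.chains)

    @property
    def is_tetraether(self) -> bool:
        return self.core in ("GDGT", "GTGT", "GMGT")

    @property
    def pendant_chains(self) -> tuple[ChainSpec, ...]:
        return tuple(c for c in self.chains if c.role == "pendant")

    @property
    def bridging_chains(self) -> tuple[ChainSpec, ...]:
        return tuple(c for c in self.chains if c.role == "bridging")

    @property
    def lipid_class(self) -> str:
        """Quantification class (which calibration standard applies)."""
        if self.core == "AR":
            return "glycosidic AR" if self.hexoses else "core AR"
        return "glycosidic tetraether" if self.hexoses else "core tetraether"

    @property
    def name(self) -> str:
        return systematic_name(self)

    def __str__(self) -> str:
        return self.name


def build_formula(descriptor: LipidDescriptor) -> ElementalFormula:
    """Derive the neutral elemental formula from the structural recipe.

    Condensation rule: sum of glycerols and chain alcohols/diols, minus one
    H2O per ether bond formed, minus H2 per cyclopentane ring (already part
    of the chain formulas), minus H2 for the GMGT C-C bridge, plus one
    C6H10O5 residue per glycosidic hexose.
    """
    total = _GLYCEROLS[descriptor.core] * GLYCEROL
    for chain in descriptor.chains:
        total = total + chain.formula()
    total = total - _ETHER_BONDS[descriptor.core] * WATER
    if descriptor.core == "GMGT":
        total = total - H2
    total = total + descriptor.hexoses * HEXOSE_UNIT
    return total


def systematic_name(descriptor: LipidDescriptor) -> str:
    """Deterministic systematic name, e.g. ``"1G-ext-iGTGT-0"``.

    ``nG-`` prefix for n hexoses, ``ext-``/``di-ext-`` for one/two extra
    isoprenoid units, the core token, and for tetraethers a suffix with the
    total cyclopentane ring count.
    """
    prefix = f"{descriptor.hexoses}G-" if descriptor.hexoses else ""
    ext = _EXT_PREFIX[min(descriptor.extensions, 2)]
    token = _CORE_TOKEN[descriptor.core]
    suffix = f"-{descriptor.total_rings}" if descriptor.core != "AR" else ""
    return f"{prefix}{ext}{token}{suffix}"


def canonical_descriptor(
    core: str, extensions: int = 0, rings: int = 0, hexoses: int = 0
) -> LipidDescriptor:
    """The canonical chain assignment for a core type and extension count.

    Extensions are placed asymmetrically, conserving one regular chain:
    GTGT/AR pendants go C20+C20 -> C20+C25 -> C25+C25, and GDGT/GMGT
    bridges go C40+C40 -> C40+C45 -> C40+C50 (one biphytanyl chain is
    retained; the mass-identical C45+C45 isomer is representable via
    explicit :class:`ChainSpec` lists but is not the canonical form).
    Rings are attributed to the first bridging chain; only the total ring
    count affects mass.
    """
    if extensions not in (0, 1, 2):
        raise ValueError(f"extensions must be 0, 1 or 2, got {extensions}")
    if core == "AR":
        if rings:
            raise ValueError("archaeols cannot carry cyclopentane rings")
        carbons = {0: (20, 20), 1: (20, 25), 2: (25, 25)}[extensions]
        chains = tuple(ChainSpec(c, "pendant") for c in carbons)
    elif core in ("GDGT", "GMGT"):
        carbons = {0: (40, 40), 1: (40, 45), 2: (40, 50)}[extensions]
        chains = (
            ChainSpec(carbons[0], "bridging", rings=rings),
            ChainSpec(carbons[1], "bridging"),
        )
    elif core == "GTGT":
        pendants = {0: (20, 20), 1: (20, 25), 2: (25, 25)}[extensions]
        chains = (
            ChainSpec(40, "bridging", rings=rings),
            ChainSpec(pendants[0], "pendant"),
            ChainSpec(pendants[1], "pendant"),
        )
    else:
        raise ValueError(f"core must be one of {CORES}, got {core!r}")
    return LipidDescriptor(core=core, chains=chains, hexoses=hexoses)


@dataclass(frozen=True)
class LibraryEntry:
    """A candidate lipid with its formula, neutral mass and adduct m/z."""

    descriptor: LipidDescriptor
    formula: ElementalFormula
    neutral_mass: float
    adduct_mzs: dict[str, float] = field(compare=False)

    @property
    def name(self) -> str:
        return self.descriptor.name


DEFAULT_ADDUCTS = ("+H", "+NH4", "+Na")

#: Cores whose bridging chains are enumerated with rings by default.  Ringed
#: GTGTs are mass-identical to GDGTs (iGTGT-1 == iGDGT-0) and GMGT-0 ==
#: iGDGT-1, so enumerating rings on those cores would create undecidable
#: mass ties; ring homologs are observed on the GDGT core.
RING_CORES = ("GDGT",)


def _make_entry(descriptor: LipidDescriptor, adducts: Sequence[str]) -> LibraryEntry:
    formula = build_formula(descriptor)
    return LibraryEntry(
        descriptor=descriptor,
        formula=formula,
        neutral_mass=monoisotopic_mass(formula),
        adduct_mzs={a: adduct_mz(formula, a) for a in adducts},
    )


def enumerate_library(
    cores: Iterable[str],
    extensions: Iterable[int] = (0, 1, 2),
    rings: Iterable[int] = (0,),
    hexoses: Iterable[int] = (0,),
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    ring_cores: Iterable[str] = RING_CORES,
    rings_on_extended: bool = False,
) -> list[LibraryEntry]:
    """Exhaustively enumerate a candidate library, sorted by neutral mass.

    Ring counts other than zero are only applied to cores in ``ring_cores``
    and, unless ``rings_on_extended`` is set, only to unextended lipids.
    The output is duplicate-free and deterministic.
    """
    cores = tuple(cores)
    extensions = tuple(extensions)
    rings = tuple(rings)
    hexoses = tuple(hexoses)
    if not cores or not extensions or not rings or not hexoses:
        raise ValueError("library configuration must not contain empty ranges")
    ring_cores = tuple(ring_cores)

    entries: dict[LipidDescriptor, LibraryEntry] = {}
    for core in cores:
        for ext in extensions:
            for ring in rings:
                if ring and core not in ring_cores:
                    continue
                if ring and ext and not rings_on_extended:
                    continue
                for hexose in hexoses:
                    d = canonical_descriptor(core, ext, ring, hexose)
                    if d not in entries:
                        entries[d] = _make_entry(d, adducts)
    return sorted(entries.values(), key=lambda e: (e.neutral_mass, e.name))


def default_library(adducts: Sequence[str] = DEFAULT_ADDUCTS) -> list[LibraryEntry]:
    """The default candidate library mirroring the observed lipid inventory.

    Archaeols with up to three hexoses; GDGT/GTGT cores with up to two
    chain extensions and zero or one hexose; ring homologs iGDGT-1..4.
    """
    entries = (
        enumerate_library(("AR",), (0, 1, 2), (0,), (0, 1, 2, 3), adducts)
        + enumerate_library(("GDGT", "GTGT"), (0, 1, 2), (0,), (0, 1), adducts)
        + enumerate_library(("GDGT",), (0,), (1, 2, 3, 4), (0,), adducts)
    )
    unique = {e.descriptor: e for e in entries}
    return sorted(unique.values(), key=lambda e: (e.neutral_mass, e.name))


def library_frame(entries: Sequence[LibraryEntry]) -> pd.DataFrame:
    """Tabulate a library (one row per lipid, one column per adduct m/z)."""
    rows = []
    for e in entries:
        row = {
            "name": e.name,
            "core": e.descriptor.core,
            "chains": "/".join(
                f"C{c.carbons}{'p' if c.role == 'pendant' else 'b'}"
                for c in e.descriptor.chains
            ),
            "rings": e.descriptor.total_rings,
            "hexoses": e.descriptor.hexoses,
            "formula": e.formula.hill(),
            "neutral_mass": e.neutral_mass,
        }
        for adduct, mz in e.adduct_mzs.items():
            row[f"mz_M{adduct}"] = mz
        rows.append(row)
    return pd.DataFrame(rows)


def write_library(entries: Sequence[LibraryEntry], path) -> None:
    library_frame(entries).to_csv(path, index=False, float_format="%.6f")


def find_entry(name: str, library: Sequence[LibraryEntry]) -> LibraryEntry:
    """Look up a library entry by systematic name."""
    for entry in library:
        if entry.name == name:
            return entry
    raise KeyError(f"no library entry named {name!r}")
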