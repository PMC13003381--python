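"""In-silico MS² fragmentation of archaeal ether lipids.

Positive-mode collision-induced dissociation of ether lipids is dominated
by neutral losses of the isoprenoid chains and of glycerol/water, plus the
complementary low-mass glycerol-monoalkyl ions:

* pendant chains leave as the alkene CnH2n (phytane/sesterterpane analog),
  or together with their glycerol as the monoalkyl glycerol ether
  C(n+3)H(2n+8)O3 (and its dehydrated form C(n+3)H(2n+6)O2);
* bridging chains leave as CnH(2n-2); follow-up losses of one glycerol and
  up to two waters produce the familiar low-mass tetraether backbone ions;
* the complementary glycerol+chain cations (e.g. C23H48O3 at m/z 373.368
  for a C20 phytanyl chain, C28H58O3 at m/z 443.446 for a C25
  sesterterpanyl chain) are the diagnostic ions distinguishing regular
  from extended chains;
* glycosidic head groups leave as C6H10O5; ammoniated precursors fragment
  to protonated product ions.

Hydrogen bookkeeping follows the printed loss formulas; intensities are
not predicted and matching is mass-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

from .formula import (
    ElementalFormula,
    FormulaError,
    MassTolerance,
    adduct_mz,
    get_adduct,
    ppm_error,
)
from .lipids import GLYCEROL, HEXOSE_UNIT, WATER, LipidDescriptor, build_formula

__all__ = [
    "FRAGMENT_KINDS",
    "DIAGNOSTIC_KINDS",
    "TheoreticalFragment",
    "FragmentMatch",
    "Spectrum",
    "predict_fragments",
    "match_spectrum",
    "fragment_score",
    "default_ms2_window",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "matches_frame",
    "write_matches",
]

FRAGMENT_KINDS = (
    "precursor",
    "chain_loss",
    "chain_glycerol_ion",
    "glycerol_loss",
    "water_loss",
    "headgroup_loss",
    "combined_loss",
)

#: Kinds counted double in :func:`fragment_score` — the structure-resolving
#: chain ions and chain losses.
DIAGNOSTIC_KINDS = frozenset({"chain_glycerol_ion", "chain_loss"})

#: Default MS² match window: 10 ppm or 0.005 Da, whichever is larger
#: (printed observed fragment masses deviate up to ~3 mDa from theory).
MS2_PPM = 10.0
MS2_DA = 0.005


def default_ms2_window(mz: float) -> float:
    return max(MS2_PPM * 1e-6 * mz, MS2_DA)


@dataclass(frozen=True)
class TheoreticalFragment:
    """A predicted MS² product ion.

    ``formula`` is the neutral skeleton of the detected cation (the ion is
    ``formula`` plus the cation of ``adduct``); ``losses`` are the neutral
    molecules lost from the precursor's neutral formula, so that
    ``formula + sum(losses)`` reconstitutes the precursor exactly.
    """

    formula: ElementalFormula
    losses: tuple[ElementalFormula, ...]
    kind: str
    annotation: str
    adduct: str
    mz: float

    def __post_init__(self) -> None:
        if self.kind not in FRAGMENT_KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")


@dataclass
class Spectrum:
    """An MS² peak list, sorted by m/z on construction."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    title: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same shape")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_peak_mz(self) -> float:
        if not len(self):
            raise ValueError("empty spectrum has no base peak")
        return float(self.mz[int(np.argmax(self.intensity))])


def _alkene(n: int) -> ElementalFormula:
    """Pendant-chain neutral loss CnH2n."""
    return ElementalFormula({"C": n, "H": 2 * n})


def _alkadiene(n: int) -> ElementalFormula:
    """Bridging-chain neutral loss CnH(2n-2)."""
    return ElementalFormula({"C": n, "H": 2 * n - 2})


def _glycerol_ether(n: int) -> ElementalFormula:
    """Glycerol-monoalkyl ether C(n+3)H(2n+8)O3 (chain + glycerol - H2O)."""
    return ElementalFormula({"C": n + 3, "H": 2 * n + 8, "O": 3})


def predict_fragments(
    descriptor: LipidDescriptor, adduct: str = "+H"
) -> list[TheoreticalFragment]:
    """Enumerate theoretical MS² product ions for a lipid and adduct.

    Product ions of ammoniated precursors are protonated (NH3 leaves with
    the first neutral loss); sodiated precursors are not modelled.  The
    output is deduplicated by (formula, adduct) and sorted by descending
    m/z, precursor first.
    """
    adduct_spec = get_adduct(adduct)
    if adduct_spec.name not in ("+H", "+NH4"):
        raise ValueError(
            f"fragmentation of {adduct_spec.name} precursors is not modelled"
        )
    neutral = build_formula(descriptor)
    precursor_mz = adduct_mz(neutral, adduct_spec)

    frags: dict[tuple[ElementalFormula, str], TheoreticalFragment] = {}

    def emit(
        losses: Sequence[ElementalFormula],
        kind: str,
        loss_labels: Sequence[str],
        ion_formula: ElementalFormula | None = None,
    ) -> None:
        losses = tuple(losses)
        if ion_formula is None:
            remaining = neutral
            try:
                for loss in losses:
                    remaining = remaining - loss
            except FormulaError:
                return  # loss path not available for this structure
        else:
            remaining = ion_formula
        if kind != "precursor" and remaining["C"] == 0:
            return  # nothing structurally informative left
        frag_adduct = adduct_spec.name if kind == "precursor" else "+H"
        if kind == "precursor":
            annotation = f"[M{adduct_spec.name}]+"
        elif kind == "chain_glycerol_ion":
            annotation = f"[{remaining.hill()}+H]+"
        else:
            annotation = "[M-" + "-".join(loss_labels) + "+H]+"
        key = (remaining, frag_adduct)
        if key in frags:
            return
        frags[key] = TheoreticalFragment(
            formula=remaining,
            losses=losses,
            kind=kind,
            annotation=annotation,
            adduct=frag_adduct,
            mz=adduct_mz(remaining, frag_adduct),
        )

    emit((), "precursor", ())

    pendants = sorted({c.carbons for c in descriptor.pendant_chains})
    bridges = sorted({c.carbons for c in descriptor.bridging_chains})
    pendant_multiset = sorted(c.carbons for c in descriptor.pendant_chains)

    # (b) pendant chains: alkene loss, glycerol-ether combined losses, and
    # the complementary glycerol+chain cations.
    for n in pendants:
        emit([_alkene(n)], "chain_loss", [f"C{n}H{2 * n}"])
        ether = _glycerol_ether(n)
        emit([ether], "combined_loss", [ether.hill()])
        dehydrated = ether - WATER
        emit([dehydrated], "combined_loss", [dehydrated.hill()])
        emit(
            [neutral - ether],
            "chain_glycerol_ion",
            [],
            ion_formula=ether,
        )

    # Loss of both pendant chains (GTGT backbone ions), optionally followed
    # by glycerol and water losses.
    if len(pendant_multiset) == 2:
        both = [_alkene(n) for n in pendant_multiset]
        labels = [f"C{n}H{2 * n}" for n in pendant_multiset]
        emit(both, "combined_loss", labels)
        emit(both + [GLYCEROL], "combined_loss", labels + ["C3H8O3"])
        emit(
            both + [GLYCEROL, WATER],
            "combined_loss",
            labels + ["C3H8O3", "H2O"],
        )
        emit(
            both + [GLYCEROL, WATER, WATER],
            "combined_loss",
            labels + ["C3H8O3", "H2O", "H2O"],
        )

    # (c) bridging chains: CnH(2n-2) loss and follow-up glycerol/water
    # losses producing the low-mass tetraether backbone ions.
    for n in bridges:
        diene = _alkadiene(n)
        label = f"C{n}H{2 * n - 2}"
        emit([diene], "chain_loss", [label])
        emit([diene, GLYCEROL], "combined_loss", [label, "C3H8O3"])
        emit(
            [diene, GLYCEROL, WATER],
            "combined_loss",
            [label, "C3H8O3", "H2O"],
        )
        emit(
            [diene, GLYCEROL, WATER, WATER],
            "combined_loss",
            [label, "C3H8O3", "H2O", "H2O"],
        )

    # (d) glycerol loss (tetraether cores have two glycerols).
    if descriptor.is_tetraether:
        emit([GLYCEROL], "glycerol_loss", ["C3H8O3"])

    # (e) water losses from the precursor.
    emit([WATER], "water_loss", ["H2O"])
    emit([WATER, WATER], "water_loss", ["H2O", "H2O"])

    # (f) glycosidic head-group losses, cumulative.
    for k in range(1, descriptor.hexoses + 1):
        label = "C6H10O5" if k == 1 else f"{k}C6H10O5"
        emit([HEXOSE_UNIT] * k, "headgroup_loss", [label])

    result = sorted(frags.values(), key=lambda f: -f.mz)
    assert all(f.mz <= precursor_mz + 1e-9 for f in result)
    return result


@dataclass(frozen=True)
class FragmentMatch:
    """A theoretical fragment assigned to an observed peak."""

    fragment: TheoreticalFragment
    peak_mz: float
    peak_intensity: float
    ppm: float


def match_spectrum(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    tol: MassTolerance | None = None,
) -> list[FragmentMatch]:
    """Assign each theoretical fragment to the nearest peak within tolerance.

    One peak may satisfy several mass-identical annotations.  With
    ``tol=None`` the default hybrid window (10 ppm or 0.005 Da, whichever
    is larger) is used.  An empty spectrum yields an empty match list.
    """
    matches: list[FragmentMatch] = []
    if not len(spectrum):
        return matches
    mzs = spectrum.mz
    for frag in fragments:
        idx = int(np.searchsorted(mzs, frag.mz))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(mzs):
                delta = abs(float(mzs[j]) - frag.mz)
                if best is None or delta < best[0]:
                    best = (delta, j)
        window = tol.window(frag.mz) if tol is not None else default_ms2_window(frag.mz)
        if best is not None and best[0] <= window:
            j = best[1]
            matches.append(
                FragmentMatch(
                    fragment=frag,
                    peak_mz=float(mzs[j]),
                    peak_intensity=float(spectrum.intensity[j]),
                    ppm=ppm_error(float(mzs[j]), frag.mz),
                )
            )
    # Deterministic order: by |ppm| then annotation, spec'd tie-break.
    matches.sort(key=lambda m: (abs(m.ppm), m.fragment.annotation))
    return matches


def fragment_score(
    matches: Sequence[FragmentMatch], fragments: Sequence[TheoreticalFragment]
) -> float:
    """Weighted fraction of predicted fragments that matched a peak.

    Diagnostic chain ions and chain losses count double.  Returns 1.0 iff
    every predicted fragment matched; 0.0 iff none did.
    """
    if not fragments:
        raise ValueError("fragment list must not be empty")

    def weight(frag: TheoreticalFragment) -> float:
        return 2.0 if frag.kind in DIAGNOSTIC_KINDS else 1.0

    matched = {(m.fragment.formula, m.fragment.adduct) for m in matches}
    total = sum(weight(f) for f in fragments)
    got = sum(weight(f) for f in fragments if (f.formula, f.adduct) in matched)
    return got / total


# -- I/O -----------------------------------------------------------------


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to a Mascot Generic Format file (TITLE, PEPMASS, peaks)."""
    records = []
    for i, s in enumerate(spectra):
        params = {"title": s.title or f"spectrum_{i}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        records.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _mgf.write(records, output=str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec.get("params", {})
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            spectra.append(
                Spectrum(
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                    precursor_mz=precursor,
                    title=params.get("title"),
                )
            )
    return spectra


def read_mzml(path, ms_level: int = 2) -> list[Spectrum]:
    """Read peak lists of a given MS level from an mzML file."""
    spectra = []
    with _mzml.MzML(str(path)) as reader:
        for rec in reader:
            if rec.get("ms level") != ms_level:
                continue
            precursor = None
            try:
                ion = rec["precursorList"]["precursor"][0]["selectedIonList"][
                    "selectedIon"
                ][0]
                precursor = float(ion["selected ion m/z"])
            except (KeyError, IndexError, TypeError):
                pass
            spectra.append(
                Spectrum(
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                    precursor_mz=precursor,
                    title=rec.get("id"),
                )
            )
    return spectra


def matches_frame(matches: Sequence[FragmentMatch]):
    """Tabulate fragment matches (peak m/z, intensity, annotation, theory, ppm)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "peak_mz": m.peak_mz,
                "intensity": m.peak_intensity,
                "annotation": m.fragment.annotation,
                "kind": m.fragment.kind,
                "formula": m.fragment.formula.hill(),
                "theoretical_mz": m.fragment.mz,
                "ppm": m.ppm,
            }
            for m in matches
        ]
    )


def write_matches(matches: Sequence[FragmentMatch], path) -> None:
    matches_frame(matches).to_csv(path, sep="\t", index=False, float_format="%.6g")
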