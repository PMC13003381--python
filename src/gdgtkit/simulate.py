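"""Synthetic feature tables, MS² spectra and calibration files.

The generator emulates the statistical structure the analysis assumes so
every stage is testable without instrument data:

* singly charged [M+H]+/[M+NH4]+/[M+Na]+ features with ppm-scale Gaussian
  mass noise (default sigma 1 ppm, matching sub-ppm instrument accuracy);
* a deliberately simple linear retention-time model anchored at iGDGT-0 =
  24.4 min in reversed phase, with extension homologs eluting ~1 min later
  per extra isoprenoid unit (and earlier in normal phase) — annotation
  only consumes the ordering, not absolute times;
* intensities proportional to amount x class response factor, with a
  small multiplicative log-normal error (default 2% CV, typical replicate
  peak-area repeatability for abundant species);
* MS² peak lists at the predicted fragment m/z with a fixed per-kind
  intensity profile (glycerol+chain ions as base peaks) and optional
  uniform-random decoy peaks, labelled in the spectrum metadata.

All randomness flows through one explicit seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import Spectrum, predict_fragments
from .lipids import LipidDescriptor, build_formula, canonical_descriptor
from .formula import adduct_mz
from .quantify import ResponseFactorTable, default_response_factors

__all__ = [
    "MixtureSpec",
    "fig1_mixture",
    "generate_features",
    "generate_ms2",
    "generate_calibration",
]

#: Base retention times (min) per core in reversed phase, anchored at
#: iGDGT-0 = 24.4 min; archaeols elute much earlier.
_RP_BASE_RT = {"AR": 18.0, "GDGT": 24.4, "GTGT": 24.3, "GMGT": 24.2}
#: Normal-phase base times (amide column); extension homologs elute earlier.
_NP_BASE_RT = {"AR": 30.0, "GDGT": 42.0, "GTGT": 41.8, "GMGT": 41.6}

#: RT shift per structural modification, min.
_RT_PER_EXTENSION = 1.0
_RT_PER_HEXOSE_RP = -0.8  # glycosidic heads elute earlier on C18
_RT_PER_HEXOSE_NP = 3.0  # and much later on the polar amide phase
_RT_PER_RING = 0.15

#: Relative ionisation weight per adduct when several are generated.
_ADDUCT_WEIGHTS = {"+NH4": 0.7, "+H": 0.2, "+Na": 0.1}

#: Per-kind MS² intensity profile (arbitrary units); glycerol+chain ions
#: are the base peaks, as observed for extended GTGTs.
_MS2_KIND_INTENSITY = {
    "chain_glycerol_ion": 100.0,
    "headgroup_loss": 80.0,
    "chain_loss": 60.0,
    "precursor": 50.0,
    "combined_loss": 40.0,
    "glycerol_loss": 30.0,
    "water_loss": 20.0,
}


@dataclass(frozen=True)
class MixtureSpec:
    """A named lipid mixture and its measurement-noise model."""

    components: tuple[tuple[LipidDescriptor, float], ...]
    mode: str = "RP"
    mass_noise_ppm: float = 1.0
    rt_noise_min: float = 0.05
    intensity_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("RP", "NP"):
            raise ValueError(f"mode must be 'RP' or 'NP', got {self.mode!r}")
        if min(self.mass_noise_ppm, self.rt_noise_min, self.intensity_cv) < 0:
            raise ValueError("noise levels must be non-negative")
        total = sum(pct for _, pct in self.components)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"component percentages must sum to 100, got {total}")


def fig1_mixture(seed: int = 0, **noise) -> MixtureSpec:
    """Preset mixture approximating the archaeal lipid pool of a
    CO2-rich cold-water geyser: glycosidic archaeols dominant (35% 2G-AR,
    15% 1G-AR), ~34% regular tetraethers, and ~10% extended lipids led by
    glycosidic extended archaeols."""
    c = canonical_descriptor
    components = (
        (c("AR", hexoses=2), 35.0),
        (c("AR", hexoses=1), 15.0),
        (c("GDGT"), 20.0),
        (c("GDGT", hexoses=1), 14.0),
        (c("AR", hexoses=3), 4.0),
        (c("AR"), 2.0),
        (c("AR", extensions=1, hexoses=1), 3.5),
        (c("AR", extensions=1, hexoses=2), 2.5),
        (c("AR", extensions=1), 0.8),
        (c("GTGT", extensions=1), 1.8),
        (c("GTGT", extensions=2), 0.8),
        (c("GTGT", extensions=1, hexoses=1), 0.3),
        (c("GTGT", extensions=2, hexoses=1), 0.2),
        (c("GDGT", extensions=1), 0.06),
        (c("GDGT", extensions=2), 0.04),
    )
    return MixtureSpec(components=components, seed=seed, **noise)


def retention_time(descriptor: LipidDescriptor, mode: str = "RP") -> float:
    """Noise-free model retention time in minutes."""
    if mode == "RP":
        rt = (
            _RP_BASE_RT[descriptor.core]
            + _RT_PER_EXTENSION * descriptor.extensions
            + _RT_PER_HEXOSE_RP * descriptor.hexoses
            + _RT_PER_RING * descriptor.total_rings
        )
    else:
        rt = (
            _NP_BASE_RT[descriptor.core]
            - _RT_PER_EXTENSION * descriptor.extensions
            + _RT_PER_HEXOSE_NP * descriptor.hexoses
            + _RT_PER_RING * descriptor.total_rings
        )
    return rt


def generate_features(
    mix: MixtureSpec,
    adducts: Sequence[str] = ("+NH4",),
    rf: ResponseFactorTable | None = None,
    total_intensity: float = 1e6,
) -> pd.DataFrame:
    """One MS1 feature per lipid per adduct, reproducible for a fixed seed.

    The returned table carries the pipeline columns (id, mz, rt_min,
    intensity) plus generator ground truth (``lipid``, ``adduct``) for
    round-trip testing.
    """
    if rf is None:
        rf = default_response_factors()
    rng = np.random.default_rng(mix.seed)
    rows = []
    k = 0
    for descriptor, pct in mix.components:
        formula = build_formula(descriptor)
        rt0 = retention_time(descriptor, mix.mode)
        for adduct in adducts:
            theo = adduct_mz(formula, adduct)
            eps = rng.normal(0.0, mix.mass_noise_ppm * 1e-6) if mix.mass_noise_ppm else 0.0
            rt = rt0 + (rng.normal(0.0, mix.rt_noise_min) if mix.rt_noise_min else 0.0)
            weight = _ADDUCT_WEIGHTS[adduct] if len(adducts) > 1 else 1.0
            intensity = (
                pct / 100.0 * total_intensity * rf.rf(descriptor.lipid_class) * weight
            )
            if mix.intensity_cv:
                intensity *= rng.lognormal(0.0, mix.intensity_cv)
            k += 1
            rows.append(
                {
                    "id": f"F{k:04d}",
                    "mz": theo * (1.0 + eps),
                    "rt_min": rt,
                    "intensity": intensity,
                    "lipid": descriptor.name,
                    "adduct": adduct,
                }
            )
    frame = pd.DataFrame(rows).sort_values("mz", kind="stable").reset_index(drop=True)
    return frame


def generate_ms2(
    descriptor: LipidDescriptor,
    adduct: str = "+H",
    noise_ppm: float = 0.0,
    seed: int = 0,
    decoy_fraction: float = 0.0,
) -> Spectrum:
    """A synthetic MS² spectrum of one lipid: every predicted fragment as a
    peak (per-kind intensity profile), plus optional decoy peaks at
    uniform random m/z.  Decoy m/z values are recorded in the metadata so
    tests can tell true from false matches."""
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValueError(f"decoy fraction must be in [0, 1), got {decoy_fraction}")
    rng = np.random.default_rng(seed)
    frags = predict_fragments(descriptor, adduct)
    mzs, intensities = [], []
    for frag in frags:
        eps = rng.normal(0.0, noise_ppm * 1e-6) if noise_ppm else 0.0
        mzs.append(frag.mz * (1.0 + eps))
        intensities.append(_MS2_KIND_INTENSITY[frag.kind])
    precursor = max(f.mz for f in frags)
    n_decoy = int(round(decoy_fraction * len(frags) / (1.0 - decoy_fraction)))
    decoy_mz = []
    for _ in range(n_decoy):
        while True:
            candidate = float(rng.uniform(100.0, precursor))
            # keep decoys away from true peaks so they stay false by design
            if all(abs(candidate - m) > 0.1 for m in mzs):
                break
        decoy_mz.append(candidate)
        mzs.append(candidate)
        intensities.append(float(rng.uniform(1.0, 10.0)))
    return Spectrum(
        mz=np.array(mzs),
        intensity=np.array(intensities),
        precursor_mz=precursor,
        title=f"{descriptor.name} [M{adduct}]+",
        metadata={"decoy_mz": decoy_mz, "lipid": descriptor.name, "adduct": adduct},
    )


def generate_calibration(
    slopes: dict[str, float] | None = None,
    amounts: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A calibration table (standard, amount_ng, area) with proportional
    response and optional multiplicative noise."""
    if slopes is None:
        slopes = {"GTGT-C46": 100.0, "1G-iGDGT-0": 100.0, "AR": 100.0, "2G-AR": 100.0}
    rng = np.random.default_rng(seed)
    rows = []
    for standard, slope in slopes.items():
        for amount in amounts:
            area = slope * amount
            if noise_cv:
                area *= rng.lognormal(0.0, noise_cv)
            rows.append({"standard": standard, "amount_ng": amount, "area": area})
    return pd.DataFrame(rows)
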