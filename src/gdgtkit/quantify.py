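"""Injection-standard semi-quantification with class response factors.

Amounts are computed relative to a co-injected standard (by default 2 ng
of the GTGT-C46 standard per injection):

    amount_i [ng/TLE] = (area_i / area_std) * amount_std / RF(class_i)

where the response factor RF of a lipid class is the through-origin
calibration slope (area per ng) of a structurally similar standard,
normalised by the injection standard's slope.  Without a user-supplied
calibration, all response factors default to 1.0 and the outputs are
strictly semi-quantitative.  Relative abundances are percentages of the
summed ng amounts and always total 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lipids import LipidDescriptor

__all__ = [
    "CLASS_STANDARDS",
    "INJECTION_STANDARD",
    "STANDARD_AMOUNT_NG",
    "ResponseFactorTable",
    "default_response_factors",
    "QuantRecord",
    "quantify",
    "through_origin_slope",
    "fit_response_factor",
    "response_factors_from_calibration",
    "abundance_report",
    "quant_frame",
]

#: Which calibration standard quantifies which lipid class.
CLASS_STANDARDS = {
    "glycosidic AR": "2G-AR",
    "core AR": "AR",
    "glycosidic tetraether": "1G-iGDGT-0",
    "core tetraether": "GTGT-C46",
}

INJECTION_STANDARD = "GTGT-C46"
STANDARD_AMOUNT_NG = 2.0


@dataclass(frozen=True)
class ResponseFactorTable:
    """Per-class response factors: class -> (standard name, RF > 0)."""

    factors: Mapping[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for cls, (standard, rf) in self.factors.items():
            if rf <= 0:
                raise ValueError(
                    f"response factor for {cls!r} ({standard}) must be positive, got {rf}"
                )

    def rf(self, lipid_class: str) -> float:
        try:
            return self.factors[lipid_class][1]
        except KeyError:
            raise KeyError(f"no response factor for lipid class {lipid_class!r}") from None

    def standard(self, lipid_class: str) -> str:
        return self.factors[lipid_class][0]


def default_response_factors() -> ResponseFactorTable:
    """Unit response factors with the default class -> standard mapping."""
    return ResponseFactorTable(
        {cls: (std, 1.0) for cls, std in CLASS_STANDARDS.items()}
    )


@dataclass(frozen=True)
class QuantRecord:
    """One quantified lipid: area -> ng amount -> relative abundance."""

    descriptor: LipidDescriptor
    area: float
    amount_ng: float
    rel_abundance_pct: float

    @property
    def name(self) -> str:
        return self.descriptor.name

    @property
    def lipid_class(self) -> str:
        return self.descriptor.lipid_class


def quantify(
    areas: Mapping[LipidDescriptor, float],
    std_area: float,
    std_amount_ng: float = STANDARD_AMOUNT_NG,
    rf: ResponseFactorTable | None = None,
) -> list[QuantRecord]:
    """Convert peak areas to ng amounts and relative abundances.

    Scaling every area (including the standard's) by a common factor
    leaves all amounts and percentages unchanged.
    """
    if std_area <= 0:
        raise ValueError(f"injection-standard area must be positive, got {std_area}")
    if rf is None:
        rf = default_response_factors()
    amounts = {
        d: (area / std_area) * std_amount_ng / rf.rf(d.lipid_class)
        for d, area in areas.items()
    }
    total = sum(amounts.values())
    records = [
        QuantRecord(
            descriptor=d,
            area=float(areas[d]),
            amount_ng=amount,
            rel_abundance_pct=100.0 * amount / total if total > 0 else 0.0,
        )
        for d, amount in amounts.items()
    ]
    records.sort(key=lambda r: -r.amount_ng)
    return records


def through_origin_slope(points: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope of area vs amount through the origin.

    Proportionality (zero analyte gives zero area) is the premise of
    ratio-based semi-quantification, hence no intercept.
    """
    pts = [(float(a), float(y)) for a, y in points]
    if len({a for a, _ in pts}) < 2:
        raise ValueError("calibration needs at least two points with distinct amounts")
    amounts = np.array([a for a, _ in pts])
    areas = np.array([y for _, y in pts])
    slope = float(np.dot(amounts, areas) / np.dot(amounts, amounts))
    if slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {slope}")
    return slope


def fit_response_factor(
    calibration: Sequence[tuple[float, float]], standard_slope: float
) -> float:
    """Response factor: calibration slope relative to the injection
    standard's slope."""
    if standard_slope <= 0:
        raise ValueError("injection-standard slope must be positive")
    return through_origin_slope(calibration) / standard_slope


def response_factors_from_calibration(
    calibration: pd.DataFrame,
    injection_standard: str = INJECTION_STANDARD,
    class_standards: Mapping[str, str] | None = None,
) -> ResponseFactorTable:
    """Build a response-factor table from a calibration file.

    ``calibration`` columns: standard, amount_ng, area (several rows per
    standard).  Each class's RF is its standard's through-origin slope
    divided by the injection standard's slope.
    """
    required = {"standard", "amount_ng", "area"}
    if not required.issubset(calibration.columns):
        raise ValueError(f"calibration table needs columns {sorted(required)}")
    if class_standards is None:
        class_standards = CLASS_STANDARDS
    slopes = {
        name: through_origin_slope(list(zip(group["amount_ng"], group["area"])))
        for name, group in calibration.groupby("standard")
    }
    if injection_standard not in slopes:
        raise ValueError(f"calibration lacks the injection standard {injection_standard!r}")
    std_slope = slopes[injection_standard]
    factors = {}
    for cls, standard in class_standards.items():
        if standard not in slopes:
            raise ValueError(f"calibration lacks standard {standard!r} for class {cls!r}")
        factors[cls] = (standard, slopes[standard] / std_slope)
    return ResponseFactorTable(factors)


_GROUP_PREDICATES = {
    "total": lambda d: True,
    "extended_fraction": lambda d: d.extensions > 0,
    "tetraether_fraction": lambda d: d.is_tetraether,
}


def abundance_report(
    records: Sequence[QuantRecord], grouping: str = "total"
) -> pd.DataFrame:
    """Percentages renormalised within a structural grouping.

    Groupings: ``total`` (all lipids), ``extended_fraction`` (at least one
    extra isoprenoid unit), ``tetraether_fraction`` (GDGT/GTGT/GMGT
    cores).  Raises if the requested group is empty.
    """
    if not records:
        raise ValueError("no quantification records to report")
    try:
        predicate = _GROUP_PREDICATES[grouping]
    except KeyError:
        raise ValueError(
            f"unknown grouping {grouping!r}; options: {sorted(_GROUP_PREDICATES)}"
        ) from None
    members = [r for r in records if predicate(r.descriptor)]
    if not members:
        raise ValueError(f"grouping {grouping!r} selects no lipids")
    total = sum(r.amount_ng for r in members)
    if total <= 0:
        raise ValueError("group total amount is not positive")
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "lipid_class": r.lipid_class,
                "amount_ng": r.amount_ng,
                "pct": 100.0 * r.amount_ng / total,
            }
            for r in members
        ]
    )


def quant_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Semi-quantitative report: area, ng/TLE amount, relative abundance."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "lipid_class": r.lipid_class,
                "area": r.area,
                "amount_ng_per_TLE": r.amount_ng,
                "rel_abundance_pct": r.rel_abundance_pct,
                "quantification": "semi-quantitative",
            }
            for r in records
        ]
    )
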