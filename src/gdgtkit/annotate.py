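"""MS1 feature annotation and homolog-series (mass-ladder) detection.

A feature table holds deconvoluted MS1 features (id, m/z, retention time,
intensity, optional inverse ion mobility).  Two complementary searches run
against it:

* **library annotation** — match each feature against the adduct m/z
  values of a candidate-lipid library within a ppm tolerance;
* **series detection** — find maximal chains of features whose m/z values
  step by a fixed repeat unit (C5H10 = 70.0783 Da within one lipid series;
  C5H12 = 72.0939 Da across the GDGT -> extended-GTGT boundary, where the
  trialkyl structure adds two hydrogens) with consistent retention-time
  ordering.  Extension homologs elute later in reversed-phase (RP) and
  earlier in normal-phase (NP) chromatography.

Series detection is discovery-oriented: overlapping maximal chains are all
reported, with no greedy pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula import MassTolerance, monoisotopic_mass, parse_formula, ppm_error
from .lipids import LibraryEntry

__all__ = [
    "FEATURE_COLUMNS",
    "MS1_TOLERANCE",
    "SERIES_TOLERANCE",
    "AnnotationHit",
    "SeriesHit",
    "validate_features",
    "read_features",
    "write_features",
    "annotate_features",
    "best_hits",
    "detect_series",
    "series_class_hypothesis",
    "annotation_frame",
    "series_frame",
]

FEATURE_COLUMNS = ("id", "mz", "rt_min", "intensity")

#: Default MS1 annotation tolerance; instrument mass accuracy is ~1 ppm.
MS1_TOLERANCE = MassTolerance(5.0, "ppm")

#: Default tolerance on consecutive series differences; looser than the
#: MS1 tolerance because the errors of two features compound.
SERIES_TOLERANCE = MassTolerance(15.0, "ppm")

#: Retention-time ordering of extension homologs per chromatography mode.
RT_DIRECTION_BY_MODE = {"RP": "increasing", "NP": "decreasing"}

_H2_MASS = monoisotopic_mass(parse_formula("H2"))


def validate_features(features: pd.DataFrame) -> pd.DataFrame:
    """Check the feature-table contract: required columns, positive m/z,
    non-negative intensity, unique ids."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns: {missing}")
    if len(features) and (features["mz"] <= 0).any():
        raise ValueError("feature m/z values must be positive")
    if len(features) and (features["intensity"] < 0).any():
        raise ValueError("feature intensities must be non-negative")
    if features["id"].duplicated().any():
        raise ValueError("feature ids must be unique")
    return features


def read_features(path) -> pd.DataFrame:
    """Read a feature table from CSV (or TSV, by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_features(pd.read_csv(path, sep=sep))


def write_features(features: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    features.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class AnnotationHit:
    """A feature assigned to a library lipid/adduct within tolerance."""

    feature_id: object
    entry: LibraryEntry
    adduct: str
    mz_observed: float
    mz_theoretical: float
    ppm: float

    @property
    def modifications(self) -> int:
        """Structural modification count used as the ranking tie-break."""
        d = self.entry.descriptor
        return d.extensions + d.total_rings + d.hexoses


def annotate_features(
    features: pd.DataFrame,
    library: Sequence[LibraryEntry],
    tol: MassTolerance = MS1_TOLERANCE,
) -> list[AnnotationHit]:
    """Annotate every feature against all library adduct m/z values.

    All candidates within tolerance are returned; per feature they are
    ranked by absolute ppm error, then by fewer structural modifications.
    """
    if not library:
        raise ValueError("candidate library must not be empty")
    validate_features(features)

    targets = []  # (mz, entry, adduct)
    for entry in library:
        for adduct, mz in entry.adduct_mzs.items():
            targets.append((mz, entry, adduct))
    targets.sort(key=lambda t: t[0])
    target_mz = np.array([t[0] for t in targets])

    hits: list[AnnotationHit] = []
    for row in features.itertuples(index=False):
        window = tol.window(row.mz)
        lo = int(np.searchsorted(target_mz, row.mz - window))
        hi = int(np.searchsorted(target_mz, row.mz + window, side="right"))
        candidates = []
        for mz_theo, entry, adduct in targets[lo:hi]:
            if abs(row.mz - mz_theo) <= tol.window(mz_theo):
                candidates.append(
                    AnnotationHit(
                        feature_id=row.id,
                        entry=entry,
                        adduct=adduct,
                        mz_observed=float(row.mz),
                        mz_theoretical=mz_theo,
                        ppm=ppm_error(float(row.mz), mz_theo),
                    )
                )
        candidates.sort(key=lambda h: (abs(h.ppm), h.modifications, h.entry.name))
        hits.extend(candidates)
    return hits


def best_hits(hits: Iterable[AnnotationHit]) -> dict[object, AnnotationHit]:
    """Best-ranked hit per feature (hits are pre-ranked per feature)."""
    best: dict[object, AnnotationHit] = {}
    for hit in hits:
        if hit.feature_id not in best:
            best[hit.feature_id] = hit
    return best


@dataclass(frozen=True)
class SeriesHit:
    """A maximal homolog series: features stepping by one repeat unit."""

    feature_ids: tuple
    mzs: tuple[float, ...]
    rts: tuple[float, ...]
    repeat_unit: str
    mean_ppm: float
    rt_direction: str

    def __post_init__(self) -> None:
        if len(self.feature_ids) < 2:
            raise ValueError("a series needs at least two members")

    @property
    def strong(self) -> bool:
        """Three or more members: the discovery-grade pattern."""
        return len(self.feature_ids) >= 3


def detect_series(
    features: pd.DataFrame,
    repeat_units: Sequence[str] = ("C5H10",),
    tol: MassTolerance = SERIES_TOLERANCE,
    rt_direction: str = "increasing",
    min_length: int = 2,
) -> list[SeriesHit]:
    """Find all maximal homolog chains for each repeat unit.

    A chain is a sequence of features whose consecutive m/z differences
    equal the repeat-unit mass within tolerance (evaluated at the mean m/z
    of the pair) and whose retention times are strictly ordered in
    ``rt_direction``.  Chains are maximal — no feature can be prepended or
    appended — and each maximal chain is reported exactly once.  The
    result is invariant under permutation of the input rows.
    """
    if rt_direction not in ("increasing", "decreasing"):
        raise ValueError(f"rt_direction must be increasing/decreasing, got {rt_direction!r}")
    validate_features(features)
    if len(features) < 2:
        return []

    order = features.sort_values(["mz", "id"], kind="stable")
    ids = order["id"].to_list()
    mz = order["mz"].to_numpy(dtype=float)
    rt = order["rt_min"].to_numpy(dtype=float)
    n = len(ids)

    results: list[SeriesHit] = []
    for unit in repeat_units:
        unit_mass = monoisotopic_mass(parse_formula(unit))
        # successor adjacency: j follows i when mz and rt step correctly
        succ: list[list[int]] = [[] for _ in range(n)]
        has_pred = [False] * n
        for i in range(n):
            for j in range(i + 1, n):
                diff = mz[j] - mz[i]
                if diff > unit_mass + tol.window(mz[j]) + 1.0:
                    break
                mid = 0.5 * (mz[i] + mz[j])
                if abs(diff - unit_mass) > tol.window(mid):
                    continue
                if rt_direction == "increasing" and not rt[j] > rt[i]:
                    continue
                if rt_direction == "decreasing" and not rt[j] < rt[i]:
                    continue
                succ[i].append(j)
                has_pred[j] = True

        # maximal chains = every source-to-sink path in the step graph
        def walk(path: list[int]) -> None:
            nexts = succ[path[-1]]
            if not nexts:
                if len(path) >= min_length:
                    deltas_ppm = [
                        1e6
                        * ((mz[b] - mz[a]) - unit_mass)
                        / (0.5 * (mz[a] + mz[b]))
                        for a, b in zip(path, path[1:])
                    ]
                    results.append(
                        SeriesHit(
                            feature_ids=tuple(ids[k] for k in path),
                            mzs=tuple(float(mz[k]) for k in path),
                            rts=tuple(float(rt[k]) for k in path),
                            repeat_unit=unit,
                            mean_ppm=float(np.mean(deltas_ppm)),
                            rt_direction=rt_direction,
                        )
                    )
                return
            for j in nexts:
                walk(path + [j])

        for i in range(n):
            if not has_pred[i] and succ[i]:
                walk([i])

    results.sort(key=lambda s: (s.repeat_unit, s.mzs[0], s.feature_ids))
    return results


def series_class_hypothesis(
    series: SeriesHit,
    features: pd.DataFrame,
    tol: MassTolerance = MS1_TOLERANCE,
) -> str:
    """Classify a series root by its 2.016 Da (H2) co-feature.

    A GTGT is two hydrogens heavier than the GDGT sharing its chain
    carbons.  If a feature sits one H2 below the series root, the root is
    the trialkyl member: ``"GTGT-series"``.  If a feature sits one H2
    above (and none below), the root is the dialkyl member:
    ``"GDGT-series"``.  Otherwise ``"unknown"``.
    """
    validate_features(features)
    root = series.mzs[0]
    mz = features["mz"].to_numpy(dtype=float)
    below = root - _H2_MASS
    above = root + _H2_MASS
    if np.any(np.abs(mz - below) <= tol.window(below)):
        return "GTGT-series"
    if np.any(np.abs(mz - above) <= tol.window(above)):
        return "GDGT-series"
    return "unknown"


def annotation_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": h.feature_id,
                "lipid": h.entry.name,
                "adduct": h.adduct,
                "formula": h.entry.formula.hill(),
                "mz_observed": h.mz_observed,
                "mz_theoretical": h.mz_theoretical,
                "ppm": h.ppm,
            }
            for h in hits
        ]
    )


def series_frame(series: Sequence[SeriesHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "members": ";".join(str(i) for i in s.feature_ids),
                "mzs": ";".join(f"{m:.4f}" for m in s.mzs),
                "rts": ";".join(f"{r:.2f}" for r in s.rts),
                "repeat_unit": s.repeat_unit,
                "length": len(s.feature_ids),
                "mean_ppm": s.mean_ppm,
                "rt_direction": s.rt_direction,
                "strong": s.strong,
            }
            for s in series
        ]
    )
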