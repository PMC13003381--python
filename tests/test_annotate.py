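"""Feature annotation, homolog-series detection and series classification."""

import numpy as np
import pandas as pd
import pytest
from seriesoracle import brute_force_series, random_feature_table

from gdgtkit.annotate import (
    annotate_features,
    best_hits,
    detect_series,
    series_class_hypothesis,
    validate_features,
)
from gdgtkit.formula import MassTolerance, monoisotopic_mass, parse_formula

C5H10 = monoisotopic_mass(parse_formula("C5H10"))


def _table(rows):
    return pd.DataFrame(rows, columns=["id", "mz", "rt_min", "intensity"])


# the discovery pattern: a trialkyl tetraether ladder stepping by one
# isoprenoid unit with ~1 min retention shifts, and the dialkyl partner
# two hydrogens below the root
DISCOVERY = _table(
    [
        ("gdgt0", 1302.326, 24.4, 9e5),
        ("gtgt0", 1304.339, 24.4, 1e5),
        ("ext", 1374.416, 25.3, 5e4),
        ("diext", 1444.495, 26.3, 2e4),
    ]
)


def test_annotate_observed_igdgt0(library):
    features = _table([("f1", 1302.326, 24.4, 1e6)])
    hits = annotate_features(features, library, MassTolerance(5, "ppm"))
    assert len(hits) == 1
    assert hits[0].entry.name == "iGDGT-0"
    assert hits[0].adduct == "+H"
    # ~+2.3 ppm against the printed 3-decimal theoretical value; slightly
    # larger against the full-precision mass the engine uses
    assert hits[0].ppm == pytest.approx(2.4, abs=0.4)


def test_annotate_no_hit_far_from_library(library):
    features = _table([("f1", 1000.000, 10.0, 1e6)])
    assert annotate_features(features, library, MassTolerance(5, "ppm")) == []


def test_annotate_exact_mass_gives_zero_ppm(library):
    target = library[0].adduct_mzs["+H"]
    features = _table([("f1", target, 10.0, 1e6)])
    hits = annotate_features(features, library)
    assert hits[0].ppm == 0.0
    assert hits[0].entry.name == library[0].name


def test_annotate_requires_nonempty_library():
    with pytest.raises(ValueError):
        annotate_features(_table([("f1", 1302.326, 24.4, 1e6)]), [])


def test_feature_table_contract_enforced():
    with pytest.raises(ValueError):
        validate_features(_table([("a", -1.0, 0.0, 1.0)]))
    with pytest.raises(ValueError):
        validate_features(_table([("a", 1.0, 0.0, 1.0), ("a", 2.0, 0.0, 1.0)]))
    with pytest.raises(ValueError):
        validate_features(pd.DataFrame({"mz": [1.0]}))


def test_detect_series_worked_example():
    series = detect_series(DISCOVERY, ("C5H10",), rt_direction="increasing")
    assert len(series) == 1
    (hit,) = series
    assert hit.feature_ids == ("gtgt0", "ext", "diext")
    assert hit.strong
    assert abs(hit.mean_ppm) < 15


def test_detect_series_respects_rt_direction():
    assert detect_series(DISCOVERY, ("C5H10",), rt_direction="decreasing") == []
    reversed_rt = DISCOVERY.assign(rt_min=[24.4, 26.3, 25.3, 24.4])
    series = detect_series(reversed_rt, ("C5H10",), rt_direction="decreasing")
    assert len(series) == 1
    assert series[0].feature_ids == ("gtgt0", "ext", "diext")


def test_detect_series_empty_and_tiny_tables():
    empty = _table([])
    assert detect_series(empty) == []
    single = _table([("a", 1000.0, 10.0, 1.0)])
    assert detect_series(single) == []


def test_detect_series_is_permutation_invariant():
    rng = np.random.default_rng(7)
    table = random_feature_table(rng, 20)
    reference = detect_series(table, ("C5H10",))
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert [s.feature_ids for s in detect_series(shuffled, ("C5H10",))] == [
        s.feature_ids for s in reference
    ]


def test_detect_series_matches_brute_force_oracle():
    rng = np.random.default_rng(2026)
    for _ in range(30):
        n = int(rng.integers(5, 31))
        table = random_feature_table(rng, n)
        found = {
            s.feature_ids
            for s in detect_series(table, ("C5H10",), MassTolerance(15, "ppm"))
            if len(s.feature_ids) <= 5
        }
        expected = brute_force_series(table, C5H10, tol_ppm=15.0)
        assert found == expected


def test_series_class_hypothesis_cases():
    series = detect_series(DISCOVERY, ("C5H10",))[0]
    assert series_class_hypothesis(series, DISCOVERY) == "GTGT-series"

    without_partner = DISCOVERY[DISCOVERY["id"] != "gdgt0"].reset_index(drop=True)
    series2 = detect_series(without_partner, ("C5H10",))[0]
    assert series_class_hypothesis(series2, without_partner) == "unknown"

    shifted = DISCOVERY.copy()
    shifted.loc[shifted["id"] == "gdgt0", "mz"] = 1304.339 - 2.10
    series3 = detect_series(shifted, ("C5H10",))[0]
    assert series_class_hypothesis(series3, shifted) == "unknown"


def test_series_class_hypothesis_partner_above_labels_gdgt():
    table = _table(
        [
            ("gdgt0", 1302.324, 27.4, 9e5),
            ("gtgt0", 1304.339, 27.2, 1e5),
            ("ext", 1372.406, 26.5, 5e4),
            ("diext", 1442.488, 25.6, 2e4),
        ]
    )
    series = detect_series(table, ("C5H10",), rt_direction="decreasing")
    roots = {s.feature_ids[0]: s for s in series}
    assert series_class_hypothesis(roots["gdgt0"], table) == "GDGT-series"


def test_zero_noise_library_recovery(library):
    """Annotating features generated from the library itself recovers
    every lipid at 0 ppm with no competing hits at 5 ppm."""
    rows = [
        (f"f{i}", entry.adduct_mzs["+H"], 20.0, 1e5)
        for i, entry in enumerate(library)
    ]
    hits = annotate_features(_table(rows), library, MassTolerance(5, "ppm"))
    assert len(hits) == len(library)
    for hit, entry in zip(hits, library):
        assert hit.entry.name == entry.name
        assert hit.ppm == 0.0


def test_one_ppm_noise_recovery_rate(library):
    """With 1 ppm Gaussian mass noise, at least 99% of features are still
    recovered as their true lipid at 5 ppm tolerance."""
    rng = np.random.default_rng(11)
    rows = []
    truth = {}
    for rep in range(10):
        for i, entry in enumerate(library):
            fid = f"f{rep}_{i}"
            mz = entry.adduct_mzs["+H"] * (1 + rng.normal(0, 1e-6))
            rows.append((fid, mz, 20.0, 1e5))
            truth[fid] = entry.name
    hits = best_hits(annotate_features(_table(rows), library, MassTolerance(5, "ppm")))
    recovered = sum(
        1 for fid, name in truth.items() if fid in hits and hits[fid].entry.name == name
    )
    assert recovered / len(truth) >= 0.99
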