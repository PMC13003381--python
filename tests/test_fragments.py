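"""In-silico fragmentation: printed diagnostic ions, element conservation,
spectrum matching and scoring."""

import numpy as np
import pytest

from gdgtkit.formula import MassTolerance, parse_formula
from gdgtkit.fragments import (
    Spectrum,
    fragment_score,
    match_spectrum,
    predict_fragments,
    read_mgf,
    write_mgf,
)
from gdgtkit.lipids import build_formula, canonical_descriptor


def _by_formula(frags, hill):
    return {f.formula.hill(): f for f in frags}.get(hill)


# printed observed m/z values for the diagnostic annotations of the
# extended tetraether lipids (positive-mode CID)
PRINTED_FRAGMENTS = [
    # (core, ext, hexoses, adduct, fragment formula, observed m/z)
    ("GTGT", 1, 0, "+H", "C28H58O3", 443.445),   # glycerol+C25 ion
    ("GTGT", 1, 0, "+H", "C23H48O3", 373.367),   # glycerol+C20 ion
    ("GTGT", 1, 0, "+H", "C71H144O6", 1094.104), # [M-C20H40+H]+
    ("GTGT", 1, 0, "+H", "C68H136O3", 1002.055), # [M-C23H48O3+H]+
    ("GTGT", 1, 0, "+H", "C63H126O3", 931.978),  # [M-C28H58O3+H]+
    ("GTGT", 1, 0, "+H", "C46H94O6", 743.712),   # backbone after both pendants
    ("GTGT", 2, 0, "+H", "C28H58O3", 443.445),
    ("GTGT", 2, 0, "+H", "C71H144O6", 1094.105), # [M-C25H50+H]+
    ("GDGT", 1, 0, "+H", "C51H104O6", 813.792),  # [M-C40H78+H]+
    ("GDGT", 1, 0, "+H", "C46H94O6", 743.713),   # [M-C45H88+H]+
    ("GDGT", 1, 0, "+H", "C43H86O3", 651.664),   # ... -C3H8O3
    ("GDGT", 1, 0, "+H", "C43H82O", 615.642),    # ... -C3H8O3-2H2O
    ("GTGT", 1, 1, "+NH4", "C91H184O6", 1374.414),  # [M-C6H10O5+H]+
    ("GTGT", 2, 1, "+NH4", "C96H194O6", 1444.499),  # [M-C6H10O5+H]+
    ("GTGT", 1, 1, "+NH4", "C28H58O3", 443.445),
]


@pytest.mark.parametrize("core,ext,hexoses,adduct,formula,observed", PRINTED_FRAGMENTS)
def test_printed_diagnostic_ions_reproduced(core, ext, hexoses, adduct, formula, observed):
    d = canonical_descriptor(core, extensions=ext, hexoses=hexoses)
    frag = _by_formula(predict_fragments(d, adduct), formula)
    assert frag is not None, f"{formula} missing from {d.name} fragment list"
    assert frag.mz == pytest.approx(observed, abs=0.005)


def test_diext_gtgt_lacks_the_c20_glycerol_ion(diext_igtgt0):
    frags = predict_fragments(diext_igtgt0, "+H")
    assert _by_formula(frags, "C23H48O3") is None
    assert _by_formula(frags, "C28H58O3") is not None


def test_symmetric_gdgt_has_single_unique_chain_loss():
    frags = predict_fragments(canonical_descriptor("GDGT"), "+H")
    chain_losses = [f for f in frags if f.kind == "chain_loss"]
    assert len(chain_losses) == 1
    assert chain_losses[0].annotation == "[M-C40H78+H]+"


def test_headgroup_loss_converts_ammoniated_precursor_to_protonated(ext_igtgt0):
    d = canonical_descriptor("GTGT", extensions=1, hexoses=1)
    frags = predict_fragments(d, "+NH4")
    precursor = max(frags, key=lambda f: f.mz)
    assert precursor.adduct == "+NH4"
    headgroup = [f for f in frags if f.kind == "headgroup_loss"]
    assert headgroup and all(f.adduct == "+H" for f in headgroup)
    assert headgroup[0].annotation == "[M-C6H10O5+H]+"


def test_sodiated_fragmentation_not_modelled(ext_igtgt0):
    with pytest.raises(ValueError):
        predict_fragments(ext_igtgt0, "+Na")


def test_element_conservation_and_mz_bound_across_default_library(library):
    """Every emitted fragment plus its neutral losses reconstitutes the
    precursor formula exactly, and never exceeds the precursor m/z."""
    for entry in library:
        for adduct in ("+H", "+NH4"):
            frags = predict_fragments(entry.descriptor, adduct)
            precursor_mz = max(f.mz for f in frags)
            neutral = build_formula(entry.descriptor)
            for frag in frags:
                total = frag.formula
                for loss in frag.losses:
                    total = total + loss
                assert total == neutral, (entry.name, adduct, frag.annotation)
                assert frag.mz <= precursor_mz + 1e-9


def test_match_spectrum_finds_diagnostic_ions(ext_igtgt0):
    frags = predict_fragments(ext_igtgt0, "+H")
    spectrum = Spectrum(
        mz=np.array([373.368, 443.446]), intensity=np.array([50.0, 100.0])
    )
    matches = match_spectrum(spectrum, frags, MassTolerance(10, "ppm"))
    matched = {m.fragment.formula.hill() for m in matches}
    assert {"C23H48O3", "C28H58O3"} <= matched


def test_match_spectrum_empty_and_out_of_tolerance(ext_igtgt0):
    frags = predict_fragments(ext_igtgt0, "+H")
    assert match_spectrum(Spectrum(np.array([]), np.array([])), frags) == []
    displaced = 443.446 * (1 + 50e-6)
    matches = match_spectrum(
        Spectrum(np.array([displaced]), np.array([1.0])),
        frags,
        MassTolerance(10, "ppm"),
    )
    assert matches == []


def test_fragment_score_limits(ext_igtgt0):
    frags = predict_fragments(ext_igtgt0, "+H")
    spectrum = Spectrum(
        mz=np.array([f.mz for f in frags]),
        intensity=np.ones(len(frags)),
    )
    assert fragment_score(match_spectrum(spectrum, frags), frags) == 1.0
    assert fragment_score([], frags) == 0.0
    with pytest.raises(ValueError):
        fragment_score([], [])


def test_fragment_score_diagnostic_weighting(ext_igtgt0):
    """Two diagnostic chain-glycerol ions (weight 2 each) matched out of a
    six-fragment list with four weight-1 members scores 4/8 = 0.5."""
    frags = predict_fragments(ext_igtgt0, "+H")
    diagnostic = [f for f in frags if f.kind == "chain_glycerol_ion"][:2]
    others = [f for f in frags if f.kind not in ("chain_glycerol_ion", "chain_loss")][:4]
    subset = diagnostic + others
    spectrum = Spectrum(
        mz=np.array([f.mz for f in diagnostic]), intensity=np.ones(2)
    )
    score = fragment_score(match_spectrum(spectrum, subset), subset)
    assert score == pytest.approx(0.5)


def test_fragment_score_monotone_in_peaks(ext_igtgt0):
    frags = predict_fragments(ext_igtgt0, "+H")
    mzs = [f.mz for f in frags]
    previous = 0.0
    for k in range(1, len(mzs) + 1):
        spectrum = Spectrum(np.array(mzs[:k]), np.ones(k))
        score = fragment_score(match_spectrum(spectrum, frags), frags)
        assert score >= previous
        previous = score
    assert previous == 1.0


def test_mgf_round_trip(tmp_path, ext_igtgt0):
    frags = predict_fragments(ext_igtgt0, "+H")
    original = Spectrum(
        mz=np.array([f.mz for f in frags]),
        intensity=np.linspace(10, 100, len(frags)),
        precursor_mz=max(f.mz for f in frags),
        title="ext-iGTGT-0 [M+H]+",
    )
    path = tmp_path / "spectra.mgf"
    write_mgf([original], path)
    (loaded,) = read_mgf(path)
    assert loaded.title == original.title
    assert loaded.precursor_mz == pytest.approx(original.precursor_mz, abs=1e-4)
    np.testing.assert_allclose(loaded.mz, original.mz, atol=1e-5)
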