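# gdgtkit

Annotation of archaeal ether lipids in high-resolution UHPLC–MS data:
constructive formula/mass modelling of archaeols (AR), glycerol dialkyl
glycerol tetraethers (iGDGTs) and the trialkyl intermediates (iGTGTs) —
including their chain-extended homologs — plus in-silico MS² fragmentation,
homolog-series (mass-ladder) detection, and injection-standard
semi-quantification.

The package is aimed at organic geochemists and lipidomics analysts who
annotate archaeal membrane lipids in feature tables exported from
high-resolution instruments, and in particular at finding the *extended*
tetraethers: iGDGTs/iGTGTs carrying one or two extra C5 isoprenoid units on
one side chain (C45 nonaprenyl or C50 decaprenyl bridges, C25
sesterterpanyl pendants), analogous to the extended archaeols of halophilic
archaea.

## Model

Lipid formulas are derived, never tabulated. A lipid is a structural
recipe — core type, chain set, ring count, hexose count — condensed as

```
formula = Σ glycerol (C3H8O3)
        + Σ pendant chains as alcohols  CnH(2n+2)O     (n ∈ {20, 25})
        + Σ bridging chains as diols    CnH(2n+2)O2    (n ∈ {40, 45, 50})
        − one H2O per ether bond (2 for AR, 4 for tetraethers)
        − H2 per cyclopentane ring − H2 for the GMGT C–C bridge
        + C6H10O5 per glycosidic hexose
```

so e.g. iGDGT-0 = 2×C3H8O3 + 2×C40H82O2 − 4×H2O = C86H172O6, and every
structural increment is exact: +C5H10 per chain extension, +C6H10O5 per
hexose, −H2 per ring, +H2 for the trialkyl (GTGT) topology. Adduct m/z
values use electron-corrected cation masses ([M+H]+, [M+NH4]+, [M+Na]+,
singly charged only).

The MS² fragmenter enumerates the neutral losses that dominate positive-ion
CID of ether lipids — pendant chains as CnH2n, bridging chains as
CnH(2n−2), glycerol, water, glycosidic hexoses — and the complementary
glycerol-monoalkyl cations (m/z 373.368 for a C20 chain, 443.446 for a C25
chain) that distinguish regular from extended structures. Every emitted
fragment satisfies element conservation against its precursor.

Homolog-series detection finds maximal chains of MS1 features separated by
a repeat unit (C5H10 = 70.0783 Da within a series; C5H12 = 72.0939 Da
across the GDGT→GTGT boundary) with consistent retention-time ordering
(later in reversed phase, earlier in normal phase). Semi-quantification is
relative to a co-injected standard (default 2 ng GTGT-C46) with per-class
response factors from through-origin calibration slopes:
`amount_i = (area_i/area_std) × amount_std / RF(class_i)`.

## Worked example

```python
import gdgtkit as g

d = g.canonical_descriptor("GTGT", extensions=1)   # ext-iGTGT-0
f = g.build_formula(d)
print(d.name, f.hill(), g.round_mz(g.adduct_mz(f, "+H")))
for fr in g.predict_fragments(d, "+H")[:6]:
    print(f"  {fr.mz:9.3f}  {fr.annotation}")
```

prints

```
ext-iGTGT-0 C91H184O6 1374.417
   1374.417  [M+H]+
   1356.406  [M-H2O+H]+
   1338.395  [M-H2O-H2O+H]+
   1282.369  [M-C3H8O3+H]+
   1094.104  [M-C20H40+H]+
   1024.025  [M-C25H50+H]+
```

i.e. the protonated extended trialkyl tetraether at m/z 1374.417, its
phytane loss at 1094.104, and further down the list the diagnostic
glycerol-sesterterpanyl ion C28H58O3 at 443.446 alongside the
glycerol-phytanyl ion C23H48O3 at 373.368 — the pair that shows one
regular and one extended pendant chain.

Series detection on four observed features reproduces the discovery
pattern in one call:

```python
import pandas as pd
feats = pd.DataFrame({"id": list("abcd"),
                      "mz": [1302.326, 1304.339, 1374.416, 1444.495],
                      "rt_min": [24.4, 24.4, 25.3, 26.3],
                      "intensity": [9e5, 1e5, 5e4, 2e4]})
(s,) = g.detect_series(feats, ("C5H10",))
print(s.feature_ids, s.repeat_unit, g.series_class_hypothesis(s, feats))
# ('b', 'c', 'd') C5H10 GTGT-series
```

The features at 1304.339/1374.416/1444.495 form one strong 3-member C5H10
ladder with increasing retention time, and the co-feature 2.016 Da (H2)
below the root identifies it as the trialkyl (GTGT) series next to its
dialkyl partner.

A shell pipeline over the same machinery:

```
gdgtkit simulate --mixture fig1 --seed 42 --out demo/
gdgtkit annotate --features demo/features.csv --tol-ppm 5 --out demo/hits.tsv
gdgtkit series   --features demo/features.csv --unit C5H10 --mode RP --out demo/series.tsv
gdgtkit quantify --areas demo/areas.csv --calib demo/calibration.csv \
                 --std-area 1e6 --std-amount 2.0 --out demo/quant.tsv
```

## Layout

- `gdgtkit.formula` — elemental-formula arithmetic, pinned mass table,
  adduct m/z, ppm tolerances
- `gdgtkit.lipids` — lipid descriptors, formula construction, systematic
  names, candidate-library enumeration
- `gdgtkit.fragments` — MS² fragment prediction, spectrum matching and
  scoring, MGF/mzML I/O
- `gdgtkit.annotate` — MS1 feature annotation, homolog-series detection,
  series classification
- `gdgtkit.quantify` — response factors and injection-standard
  semi-quantification (ng per total lipid extract, relative abundances)
- `gdgtkit.simulate` — synthetic feature tables, MS² spectra and
  calibration files for end-to-end testing
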