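# Methods

## Scope and model

gdgtkit annotates archaeal ether lipids — archaeols (AR), isoprenoidal
glycerol dialkyl glycerol tetraethers (iGDGTs), the trialkyl intermediates
(iGTGTs) and, in a mass-only way, the C–C-bridged GMGTs — in
positive-mode high-resolution UHPLC–MS feature tables and MS² spectra.
Its structural model is deliberately constructive: a lipid is a recipe
(core topology, chain carbon numbers, cyclopentane ring count, hexose
count) and everything measurable — elemental formula, neutral
monoisotopic mass, adduct m/z, fragment inventory, systematic name — is
derived from the recipe. That makes every structural increment exact by
construction: +C5H10 per chain extension, +C6H10O5 per glycosidic hexose,
−H2 per ring, +H2 for the trialkyl topology (one bridging chain replaced
by two pendant chains of the same total carbon), −H2 for the GMGT bridge.

Assumptions: fully saturated isoprenoid chains; pendant chains of 20 or
25 carbons, bridging chains of 40, 45 or 50; at most 8 rings, attributed
to bridging chains without positional detail (only the total affects
mass); hexose (glucose) head groups only; singly charged positive adducts
(+H, +NH4, +Na). Out of scope: stereochemistry, unsaturation,
hydroxylated or methylated variants, crenarchaeol's cyclohexane ring,
butanetriol/pentanetriol backbones, isotope patterns, negative-ion mode.

## Mass conventions

The atomic-mass table is pinned in `formula.py` (C 12.000000000,
H 1.00782503, N 14.00307401, O 15.99491462, Na 22.98976928; electron
0.00054858 Da) so theoretical values are stable across environments.
Cation masses are electron-corrected (proton = 1.00727645 Da); without
this correction reported m/z values would be ~0.55 mDa high, which at
sub-ppm instrument accuracy is a visible bias. Reported m/z values are
rounded half-even to 3 decimals; all internal arithmetic is full double
precision. Vendor software may use a slightly different mass compilation,
so printed *observed* literature values can deviate from our theoretical
values by a few tenths of a mDa; such discrepancies are expected and are
never "fixed" by tuning constants.

## Fragmentation model

`predict_fragments` enumerates, per lipid and adduct:

* pendant-chain neutral losses as the alkene CnH2n, and the combined loss
  of the chain with its glycerol as the monoalkyl glycerol ether
  C(n+3)H(2n+8)O3 (plus its dehydrated form C(n+3)H(2n+6)O2);
* the complementary glycerol-monoalkyl cations C(n+3)H(2n+8)O3 — the
  diagnostic ions (m/z 373.368 for C20, 443.446 for C25) that resolve
  regular from extended pendant chains;
* loss of both pendant chains, optionally followed by glycerol and up to
  two waters (the familiar tetraether backbone ions near m/z 743.7,
  651.7, 615.6);
* bridging-chain losses as CnH(2n−2), with the same glycerol/water
  follow-ups;
* glycerol loss, one and two water losses, and cumulative hexose losses
  (ammoniated precursors yield protonated product ions; sodiated
  precursors are not fragmented — no informative CID chemistry is
  modelled for them).

Hydrogen bookkeeping follows the loss formulas above verbatim; no
alternative H-transfer channels are modelled, and intensities are not
predicted (matching is mass-only). Every fragment carries its neutral-loss
list, and the identity `fragment + Σ losses = precursor` is enforced by
the test suite over the whole default library. A small caveat: the
backbone and dehydrated-ether ions are our best element-conserving
candidates for low-mass ions that the literature reports without printed
formulas; they reproduce those observed values within ~3 mDa but remain
unverified as structures. One literature value (1002.067 for the doubly
extended GTGT) disagrees with its best candidate by 11 mDa — the
analogous singly extended value matches to 1 mDa, so we treat it as a
likely misprint and do not assert it.

Spectrum matching assigns each theoretical fragment to the nearest peak
within tolerance; the default MS² window is max(10 ppm, 0.005 Da),
reflecting that printed observed fragment masses deviate from theory by
up to ~3 mDa. One peak may satisfy several mass-identical annotations.
Ties are broken by smaller |ppm|, then lexicographic annotation string —
determinism over chemistry. `fragment_score` is the weighted fraction of
matched fragments with chain ions and chain losses counted double,
operationalising "the diagnostic pattern supports the structure".

## Feature annotation and series detection

MS1 annotation compares each feature against every library adduct m/z
within a ppm tolerance (default 5 ppm, a conservative multiple of the
~1 ppm instrument accuracy); all candidates are kept, ranked by |ppm|
then by fewer structural modifications.

Series detection searches for homolog ladders: maximal chains of features
whose consecutive m/z differences equal a repeat-unit mass — C5H10
(70.0783 Da) within one series, C5H12 (72.0939 Da) across the
GDGT→extended-GTGT boundary — within a tolerance evaluated at the pair's
mean m/z (default 15 ppm, looser than the MS1 tolerance because two
feature errors compound), and whose retention times are strictly ordered
in the mode's elution direction (reversed phase: extensions elute later;
normal phase: earlier). Repeat-unit masses are computed from formulas,
never hard-coded. Chains are maximal (no feature can be prepended or
appended) and overlapping chains are all reported — recall over precision
for a discovery tool. Two members suffice for reporting; three or more
are flagged "strong". A brute-force subset-enumeration oracle cross-checks
the detector in the tests.

`series_class_hypothesis` uses the 2.016 Da (H2) offset between dialkyl
and trialkyl tetraethers: a co-feature one H2 below the series root labels
the root a GTGT, one H2 above labels it a GDGT, otherwise unknown. The
offset tolerance mirrors the MS1 tolerance (the literature states none).

## Semi-quantification

Amounts are computed relative to a co-injected standard (default 2 ng of
GTGT-C46 per injection): `amount_i = (area_i/area_std) × amount_std /
RF(class_i)`. Response factors are through-origin least-squares
calibration slopes normalised by the injection standard's slope —
zero analyte must give zero area, and ratio-based semi-quantification
presumes proportionality. The default class→standard mapping is 2G-AR for
glycosidic ARs, AR for core ARs, 1G-iGDGT-0 for glycosidic tetraethers,
GTGT-C46 for core tetraethers, with RF = 1.0 until a calibration file is
supplied; outputs are labelled semi-quantitative accordingly. Relative
abundances are percentages of the summed ng amounts (not of
response-corrected areas) and sum to 100 ± 0.01; grouped reports
renormalise within a predicate (all lipids / extended lipids /
tetraethers). All results are invariant under common scaling of the areas.

## Default library

`default_library()` enumerates ARs with 0–2 extensions and 0–3 hexoses,
GDGT/GTGT cores with 0–2 extensions and 0–1 hexoses, and ring homologs
iGDGT-1..4 — 28 candidates mirroring the inventory the package targets.
Two policy choices keep the library mass-resolvable (minimum mass gap
> 0.05 Da, so zero-noise annotation is unambiguous): rings are enumerated
on the GDGT core only (a ringed GTGT is mass-identical to a GDGT, and
GMGT-0 to iGDGT-1), and only on unextended lipids (whether extended
chains carry rings is an open question; the model permits such
descriptors, the default library excludes them). The doubly extended
GDGT is canonically modelled with one C40 and one C50 bridge — the
structural trend conserves one biphytanyl chain — while the mass-identical
C45+C45 isomer remains representable.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes, which bounds what passing tests show about real data:

* one feature per lipid per configured adduct, with Gaussian ppm-scale
  mass noise (default σ = 1 ppm, the instrument-accuracy scale);
* a linear retention-time model anchored at iGDGT-0 = 24.4 min in
  reversed phase, +1 min per extension (reversed in normal phase),
  with small Gaussian RT noise — annotation consumes only the ordering,
  so the model is deliberately simple;
* intensities proportional to amount × class response factor with 2%
  multiplicative log-normal error (typical replicate peak-area
  repeatability for abundant species);
* MS² peaks at predicted fragment m/z with a fixed per-kind intensity
  profile (glycerol+chain ions as base peaks) and optional decoy peaks,
  recorded in the spectrum metadata.

Not emulated: chromatographic peak shapes and co-elution, isotope
envelopes, in-source fragmentation, matrix effects, detector saturation,
ion-mobility behaviour. Consequently the end-to-end tests demonstrate the
pipeline's internal consistency (generate → annotate → quantify recovers
the composition within noise, with zero false identifications at 5 ppm),
not detection performance in crowded real spectra.

The `fig1` preset mixes 35% 2G-AR, 15% 1G-AR, 34% regular tetraethers,
~10% extended lipids (dominated by glycosidic extended ARs, with
ext-iGTGT-0 at 1.8% and di-ext-iGTGT-0 at 0.8% of the pool) and 6% other
glycosidic ARs — a realistic archaeal lipidome of a CO2-rich subsurface
aquifer. All randomness flows through one explicit seed; no global state.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: the default
library (28 lipids × 3 adducts), series-detection oracle checks on 100
random tables of ≤ 30 features, and single-mixture round trips — the
quantities reported by `scripts/acceptance.py` are closed-form theoretical
values, independent of problem size. Degenerate inputs are defined, not
special-cased: empty spectra match nothing, an empty feature table has no
series, a single-lipid report is 100%, empty library ranges and
non-positive standards raise.

## Known limitations

* Response factors default to 1.0; absolute accuracy requires a user
  calibration, and outputs are semi-quantitative throughout.
* Fragment prediction is rule-based and mass-only; it cannot rank
  isomers that share a fragment inventory (e.g. C45+C45 vs C40+C50
  bridges), only flag them as mass-identical.
* Series detection reports all maximal chains; in dense feature tables
  with many near-repeat spacings this favours recall and can emit
  overlapping candidate ladders that need downstream curation.
* The 2 Da GDGT/GTGT classification inspects single co-features; it does
  not deconvolve overlapping isotope envelopes, which on real data are
  the main confounder at that offset.
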