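# Methods

`lipidmrm` implements the computational core of an extensive targeted
(MRM) lipidomics workflow for grape berries: library generation, mass
arithmetic, annotation validation, internal-standard semi-quantification,
bioanalytical validation statistics, and the downstream ripening-trend
analysis. This note records the models, the defaults and the reasoning
behind the genuinely open design choices.

## Chain space and species combinatorics

Plant-lipid acyl chains are modelled as (carbons, double bonds) pairs over
a configurable rectangle; the default is even carbon numbers 14–22 with
0–6 double bonds, giving 5 × 7 = 35 chains. A lipid species is a class
scaffold plus an unordered *multiset* of chains, because fragmentation on
a triple quadrupole cannot resolve sn positions: two-chain classes (DG,
MGDG, DGDG, PA, PC, PE, PG, PI, PS) therefore enumerate C(36,2) = 630
species and TG enumerates C(37,3) = 7770. Sphingolipid classes (SM and
the six-member ceramide family) carry a fixed sphingoid base — sphingosine
(d18:1) for CER/glcCER/lacCER/SM, sphinganine (d18:0) for the dihydro
classes, distinguishable by their 264.1 vs 266.1 long-chain-base
fragments — plus one variable N-acyl chain, so each contributes 35
species. Two counts printed in the source method are *not* reproducible
from any stated chain space and are pinned in the test suite as known
discrepancies rather than silently matched: acylcarnitines (48 printed;
35 derivable, the chain space that would give 48 is not described, so the
class stays configurable) and the three-chain count (7700 printed where
the multiset arithmetic gives 7770).

## Mass arithmetic

Neutral monoisotopic masses are assembled as

    M = scaffold + Σ free fatty acids − n_linkages × H₂O,

where scaffolds (glycerol; glycerophosphate/-choline/-ethanolamine/
-glycerol/-inositol/-serine; mono-/di-galactosylglycerol; carnitine; the
sphingoid bases with optional glucosyl/lactosyl/phosphorylcholine
extensions) are stored as elemental compositions with an embedded atomic
mass table (CODATA/AME2020 monoisotopic values). A release-gate test
compares one species per class against an independent whole-formula
summation (pyteomics) to < 0.001 Da. Adducts ([M+H]⁺, [M−H]⁻, [M+Na]⁺,
[M+HCOO]⁻, and protonation-with-water-loss written [M+H−18]⁺, taken as
the exact dehydration delta 18.0106 Da rather than nominal 18) include
the electron-mass correction, so [M+H]⁺ + [M−H]⁻ = 2M holds to numerical
precision.

Product ions follow the per-class rules: head-group constants (184.1 for
the phosphocholine cation of LPC/SM, 264.1/266.1 for the sphingoid bases,
85.1 for acylcarnitines) are exported **verbatim as printed** — the
artifact reproduces the published method — while a `recompute_fixed`
switch exposes the exactly computed values (184.0733, 264.2686, 266.2842,
85.0284). Chain-dependent products are the deprotonated carboxylate of
the monitored chain (negative-mode phospholipids), the neutral loss of a
free fatty acid from the sodiated precursor (DG/TG and, with
rearrangement, MGDG/DGDG), or — for MG — loss of neutral glycerol from
[M+H]⁺, which yields the textbook acylium ion (MG 16:0 → 239.237); the
literal radical-formula reading of the printed notation ([M−C₃H₇O₃]⁺) is
available via `glycerol_loss_as_radical` and differs by < 0.001.

## Transition-list assembly

Because species are multisets, the "sn2 chain" of a published transition
is a convention, not a structure determination. The builder's default
`leaving_policy="designated"` emits one transition per species monitoring
the highest-sorted chain (most carbons, then most double bonds) — the
one-MRM-per-compound convention that reproduces the published per-class
counts (630 per two-chain class, 7770 TG) — while `"all"` emits every
distinct chain as a candidate leaving group for auditing. Deduplication
merges transitions whose (Q1, Q2) collide at a configurable decimal
precision, keeping all contributing species ids (every exported pair
remains recomputable from its species id). At one decimal the full TG
list collapses from 7770 to 1981 unique pairs; the published figure of
1834 is not reproduced by any plain rounding rule tested (precisions
1–4), so the discrepancy is documented and asserted rather than tuned
away. Exports are byte-stable delimited text with a `1dp` (instrument
convention) or `exact` (4-decimal) dialect; the 21 internal standards —
deuterated or odd-chain surrogates, the six ceramide classes sharing one
labelled ceramide — are flagged, with the deuterium label placed on the
mass-relevant chain so fragment arithmetic carries the shift correctly.

## Kendrick grid validation

With KM = m/z × 14/14.01565 and KMD = nearest-integer(KM) − KM, CH₂
homologs share a KMD exactly. In a KMD-vs-RT plot of a reversed-phase
separation, same-double-bond series form horizontal lines whose RT grows
with carbon number, and same-carbon series form diagonals whose RT
shrinks with unsaturation. `grid_check` flags KMD deviations from the
series median beyond `kmd_tolerance` as `horizontal_violation` and RT
inversions beyond `rt_tolerance` (both members of the offending adjacent
pair) as `diagonal_violation`. Defaults: `kmd_tolerance = 0.002` and
`rt_tolerance = 0.05` min. The KMD tolerance is set just below the shift
caused by the smallest mis-annotation worth catching — a ¹³C isotope
mis-pick (+1.00335 Da) moves the CH₂-based KMD by only 0.0022, while one
double bond moves it by ~0.0125 — and far above the numerical noise of
the default theoretical-Q1 mode (an observed-m/z mode accepts measured
values instead). Series with fewer than three members cannot support a
decision and pass with a `short-series` note; duplicate (class, C, DB)
entries are rejected as ambiguous.

## Semi-quantification and validation statistics

Concentrations assume equal molar response within a class:
conc = area/area(IS) × IS amount (µg) / sample weight (g), in µg/g fresh
weight; the default IS amount (150 µg) reflects spiking 15 µL of a
10 mg/mL mix into ~100 mg of powder and is configuration, not code.
Missing values are imputed uniformly on (0, min_observed/2) per compound,
reproducibly under a seed. Recovery is the mean over replicates of
measured/expected per spike level (0.1/0.5/1 mg/L, five replicates),
then the mean over the three levels. The linear range is the longest
contiguous run of calibration points (ties broken toward the lowest
start) with R² ≥ 0.99 and back-calculated accuracy within ±20% — limits
chosen to match standard bioanalytical acceptance norms, as the source
text states none; LOQ is the lowest point of that run, and "LOD =
3.3 × (S/N)" is read dimensionally as the concentration at which the
predicted signal-to-noise reaches 3.3 (3.3 × noise/slope), the standard
interpretation of an otherwise unitless phrase. The compound filter
retains repeatability CV ≤ 20% (inclusive) *and* a clean Kendrick flag;
intra-day (≤ 15%) and inter-day (≤ 20%) CVs are reported descriptively by
default and become exclusion criteria with `apply_day_cv=True`, since the
published filter's use of them is ambiguous.

## Ripening analysis

The study matrix is log-transformed (imputation guarantees positivity),
then unit-variance scaled by default; Pareto scaling (divide by √sd) is
selectable, and exploratory PCA always uses log + Pareto via SVD, with
zero-variance compounds dropped (their scaling is undefined). PLS
component count is chosen by 10-fold cross-validated RMSEP with a
one-standard-error tie-break toward fewer components. Reported
coefficients are on the standardized-predictor scale so they are
comparable across compounds. Predictive performance is the median
Q² = 1 − PRESS/TSS (TSS centred on the training mean) over repeated
random 2/3–1/3 splits (1000 by default); the permutation null repeats
this with the response independently permuted per iteration. The null
reuses the component count selected on the observed data by default:
re-selecting inside each permutation is statistically purer but ~50×
more expensive and does not move the null's location in practice;
`reselect_components=True` enables it. Class-level trends use the 25th
and 75th percentiles (linear interpolation) of the coefficient
distribution as thresholds with *strict* tail membership, so a degenerate
all-equal coefficient vector yields zero tail fractions; fractions are
invariant to monotone rescaling of the coefficients by construction.

## Synthetic-data generator

The generator emulates the study design the package targets: 13
maturation points with five biological replicates each (three for the
last two points, 59 study samples), pooled QC injections (6 by default),
a linear 14→22 °Brix trajectory (only monotonicity matters downstream),
per-class internal standards at nominally constant area, log-normal
multiplicative noise with unit mean (default CV 10%, inside the 2–21%
repeatability range targeted methods report), and 5% random missingness.
Trends are planted as linear-in-°Brix log-abundance slopes of fixed sign
per class — up for LPC/LPE/PE/PG/PI, down for CER/MG/LPG/DGDG/MGDG, flat
otherwise — with per-compound magnitudes drawn from 0.5–1.5 × 0.08 per
degree Brix. The planted truth (slopes, baselines, and the concentration
matrix implied by the realised IS areas) is returned alongside, making
`semi_quantify ∘ simulate` an exact identity at any noise level. The
spike-design generator mirrors the recovery estimator's forward model.
What the generator does *not* emulate — retention-time drift, censoring
of low areas rather than random missingness, correlated compound noise,
ion suppression — bounds what passing tests show about real data: they
validate the estimators' correctness and calibration, not matrix-effect
robustness.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is reproducible
bit-for-bit. The test suite exercises the full 14 021-transition default
build, 1000-repeat recovery calibration, and 20 simulated maturation
studies with 200-split Q²/permutation distributions — sizes chosen so the
whole suite runs in well under a minute of PLS time while keeping Monte
Carlo error far below the tolerances asserted. The real study's headline
regression values (R² = 0.889, median Q² = 0.855, permutation −0.033;
412 of 1045 compounds validated) depend on raw data that was never
deposited and are therefore not reproduced here; the machinery that
produced them is validated on the synthetic benchmark instead.

## Known limitations

- Odd-chain, ether-linked (O-/P-), hydroxylated and oxidized species,
  sterols, prenols and sulfolipids (e.g. SQDG) are out of scope.
- No isotope-pattern simulation, collision-energy prediction,
  retention-time prediction, scheduled-MRM windows or vendor binary
  formats.
- Peak integration is upstream: areas are inputs.
- The acylcarnitine chain space (printed count 48) and the TG
  deduplication rule (printed count 1834) of the source method cannot be
  derived from its description; both are left configurable and the
  shipped defaults document the difference.
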