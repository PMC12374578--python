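# Methods

This note records the models behind `segscan`, the defaults that matter, and
the choices made where the design was genuinely open.

## Trap physics

Radial ion motion in an RF-only linear quadrupole trap obeys the Mathieu
equation with a = 0 and

    q = 4 z e V / (m Ω² r₀²),

V the zero-to-peak RF amplitude, Ω = 2π·f_RF, r₀ the field radius, m the ion
mass (m/z × u for singly charged metabolites — the package assumes z = 1
throughout, appropriate for m/z 50–500 small molecules). The secular
frequency is f = β·f_RF/2, with β(q) the Floquet exponent. β is computed from
the a = 0 characteristic equation in continued-fraction form,

    β² = q²/((2−β)² − q²/((4−β)² − …)) + q²/((2+β)² − q²/((4+β)² − …)),

truncated at depth 64 (terms decay like q²/(2k)⁴, so the truncation error is
far below the 1e-12 solver tolerance for q < 0.908) and solved by bracketed
root finding on β ∈ (0, 1). For q < 1e-6 the adiabatic limit β = q/√2 is
returned directly. The test suite checks β against an independent oracle that
integrates the Mathieu equation over one period and extracts the Floquet
exponent from the monodromy-matrix trace; agreement is ~1e-11 across the
stability region, against a 1e-6 requirement.

Defaults: f_RF = 1033 kHz, ejection AC = 376 kHz, centre-ion q = 0.65,
stability limit 0.908. The field radius is not a published instrument
parameter; the default r₀ = 4 mm is typical for miniature linear traps, and
every quantity the package validates (q values, frequency ratios, round
trips) is ratio-based, so r₀ cancels. Ions at or beyond the stability limit
raise `UnstableIonError` rather than clamping — silent clamping would corrupt
SWIFT designs.

## SWIFT synthesis

An isolation waveform is built in the frequency domain on the FFT grid of the
chosen duration (default 10 ms at 5 MHz sampling, i.e. 100 Hz bins): unit
magnitude across the excitation band, zero inside the notch, inverse
transformed and normalized to unit peak (absolute voltage scaling is hardware
territory). The excitation band spans the secular frequencies of q = 0.05 to
q = 0.9 — heavier ions than the band edge are effectively undriven, lighter
ones are already unstable. The notch edges are the secular frequencies of the
window's m/z bounds at the RF amplitude that places the window centre at
q = 0.65; since secular frequency falls with m/z, the lower notch edge comes
from the *upper* m/z bound.

Open design points and their resolutions:

- **Phase.** Quadratic phase across excitation bins, the standard SWIFT
  phase-scrambling scheme; it reduces the crest factor from ~92 (all cosines
  in phase) to ~3. Zero phase is retained as an option because the contrast
  itself is a useful test.
- **Notch edges.** A raised-cosine taper over 2 bins just outside the notch
  suppresses Gibbs leakage into it. With the taper, measured in-notch
  rejection is limited only by float round-off (reported capped at 300 dB);
  the acceptance bound is 40 dB.
- **Feasibility guards.** Synthesis refuses Nyquist violations and durations
  whose bin width exceeds a quarter of the notch (an unresolvable notch);
  `cutoff_frequencies` raises `SegmentTooWideError` when the window's low-m/z
  edge would sit beyond the stability limit at the centre-ion voltage — this
  physical limit, not a fixed width cap, is what bounds usable window widths
  (about 0.57× the centre m/z at q_centre = 0.65).

## Instrument simulation

The simulator renders a ground-truth profile (m/z, ion arrival rate in
ions/ms) into spectra: each species is a Gaussian of 0.4 Da FWHM (the
instrument's resolving power) on a 0.05 Da grid (≥8 samples per FWHM), with
peak area proportional to trapped ions. Grids are aligned to absolute
multiples of 0.05 Da so segment grids stitch seamlessly.

Trapped charge is N = (in-window arrival rate) × (injection time). Space
charge is modelled hinge-linearly in the relative overload
x = max(0, N/capacity − 1):

- σ → σ₀(1 + b·x) (broadening),
- centroid → m/z + s·x (upward shift, matching the observed direction),
- heights → h/(1 + c·x) (saturation).

A hinge-linear form is the simplest model that reproduces the benchmark
behaviour — no distortion at a 35 ms injection, severe distortion at 60 ms —
and it makes distortion monotone in injection time by construction. The
`SpaceChargeModel.calibrated` constructor fixes the coefficients from a
profile's charge budget: capacity equals the charge delivered in 38 ms (so
35 ms scans are clean), and at 60 ms the coefficients produce a palmitate
[M-H]⁻ peak (true m/z 255.233) reading at m/z 257.0, a doubled FWHM, and
4× height suppression. These calibration targets are fixture choices encoding
the qualitative phenomenon, not fitted physics.

The bundled `reference_profile` holds ~180 species over m/z 50–500: a dozen
named anchors at their true [M-H]⁻ adduct masses (lactate, glutamate,
aspartate, N-acetylaspartate, 2-hydroxyglutarate, xanthine, allantoin,
tyrosine, the C16/C18 fatty acids, and a fixed M+1 isotopologue of palmitate
at 17% — a C16 carbon envelope; isotope fine structure is otherwise out of
scope) plus anonymous filler with log-uniform abundances spanning three
orders of magnitude, scaled so the total arrival rate is exactly
30 000 ions/ms. Fixing the total makes the charge budget, and hence the
space-charge calibration, independent of the filler draw. Allantoin's rate
(60 ions/ms) puts its clean-scan apex at ~9000 counts — above the
5000-count detection threshold in a segment scan, but below it in an
overloaded full scan after saturation and broadening, reproducing the
segment-scan sensitivity advantage for low-abundance species.

Noise is multiplicative log-normal on peak heights (default 5%) plus an
additive baseline (default SD 5 counts). All generators are keyed on
(seed, window), so identical settings give bit-identical spectra and a
single all-covering window reproduces the full scan exactly.

What the simulator does *not* emulate: chromatographic or matrix effects,
ion-optical transmission curves, isotope envelopes beyond the single M+1
option, detector nonlinearity, and chemical noise structure. Passing tests
therefore demonstrate the correctness of the acquisition logic and the
statistics under controlled conditions, not instrument-level validity on
real tissue.

## Segment processing

Windows step by (width − overlap) from the range start until the last window
reaches the range end (20 Da / 5 Da defaults give 29 windows over m/z
65–500). Merge boundaries default to overlap midpoints — the points farthest
from window edges, where SWIFT edge effects would live. Merging assigns each
output point to exactly one segment via half-open intervals [low, high), so a
point exactly on a boundary belongs to the higher window; intensities are
never averaged or rescaled across segments, because adjacent windows are
acquired at different trapped charges and averaging would mix calibrations.

Peak picking searches ±0.3 Da around the target for interior points strictly
greater than both neighbours; among several, the most intense wins, intensity
ties break to the candidate nearest the target (distances rounded at 1e-9 Da
so grid float jitter cannot decide a genuine tie), and remaining ties to the
lower m/z — fixed tie-breaks keep the pipeline deterministic. With no local
maximum the window mean is reported, flagged `window_mean`.

Relative intensity is peak area over the total area of the containing
spectrum (the full scan, or the segment the peak falls in). The peak's
extent runs from the apex to the first local minimum on each side or ±3×FWHM,
whichever comes first; a straight-line local baseline between the extent
endpoints is subtracted by default (toggleable — whether the area should be
baseline-corrected is genuinely open, and the zero-baseline case is
unaffected). FWHM is linear interpolation of the half-height crossings,
raising `UnresolvedPeakError` if a crossing is not bracketed within 1 Da.

## Annotation

Matching is |peak m/z − (monoisotopic mass + adduct mass)| ≤ 0.2 Da, with
[M+H]⁺/[M−H]⁻ defaults (±1.00728 Da; the electron mass, ~5e-4 Da, is
neglected as far below the tolerance) and a configurable adduct table. All
within-tolerance candidates are kept, ranked by |mass error| — at unit
resolution a best-only policy would hide genuine ambiguity; deduplication by
compound id happens when counting identifications. The bundled table's
masses are computed from molecular formulas with standard isotope masses
(accurate to ~1e-5 Da), so table error is negligible against the tolerance.

## Statistics

- **Volcano.** Per-feature two-sample t-test; Welch (unequal variances) by
  default since relative-intensity variances differ across groups, with the
  classical equal-variance test available. Raw p-values gate significance
  (p < 0.05 together with FC > 1.5 or < 2/3); a Benjamini–Hochberg switch
  exists but is off by default, matching the raw-p convention of the joint
  gate. Zero-variance features yield NaN p and are flagged not significant.
- **Cohort generator.** Log-normal relative intensities with per-feature
  log-means drawn once per cohort and per-sample log-SD 0.35 (≈36% CV,
  representing combined technical and biological variability for
  direct-sampling MS), planted features shifting the second class's log-mean
  by ln(FC). Balanced or imbalanced class counts.
- **Classifier.** XGBoost with fixed, recorded hyperparameters (150 trees,
  depth 3, learning rate 0.1, subsample 0.9, hist method, single thread) —
  small trees and moderate shrinkage suit cohorts of tens of samples.
  Per-sample weights are n_total/(n_classes·n_c), the inverse-frequency
  convention. Stratified 80:20 split and stratified 5-fold CV, both
  deterministic under the seed. "Confidence" is the predicted class
  probability of the predicted class, the quantity reported per specimen.
- **ROC/AUC.** Computed in-house from midranks (Mann–Whitney U over
  n_pos·n_neg pairs, ties counted ½) rather than delegated, so the test
  suite can check it against both brute-force pair counting and
  scikit-learn as independent routes. AUC confidence intervals are
  percentile bootstrap (2000 resamples), and reports label the method,
  since a parametric interval would be an undocumented alternative.

## Problem sizes in tests and the acceptance script

Null calibration uses 200 replicates of 1000-feature, 20-per-group cohorts
(200 000 feature-tests); classifier recovery uses 20 seeds of 60-sample
cohorts with ten 2-fold planted features; merge conservation uses 100 random
profiles of 10–30 resolvable species; AUC cross-checks use 1000 random
instances of n ≤ 50. These sizes give stable estimates (e.g. the null
false-positive rate is estimated to ±0.0005) while keeping a full run in the
tens of seconds.

## Known limitations

- β(q) covers the a = 0 line only; DC offsets (a ≠ 0), higher-order field
  corrections and collisional cooling are out of scope.
- The space-charge model is phenomenological; it reproduces directions and
  monotonicity, not ion-cloud physics.
- Annotation is MS1-only; MS/MS confirmation is not modelled.
- mzML support is a minimal adapter (single profile spectrum, common
  encodings); delimited text is the canonical format.
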