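# Methods

This note documents the models, rules, parameters and numerical choices
behind `umrm`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Acquisition model

The workflow assumes pooled-sample discovery data: a centroided MS1
feature table (m/z, retention time, intensity, polarity) and
data-dependent MS/MS spectra acquired at four discrete collision
energies, 0/10/20/40 eV, with the isolated precursor m/z, retention time
and collision energy recorded per MS2 scan. The 0 eV spectra are not
assumed fragment-free: they serve as a low-energy reference that reveals
ions formed in the source rather than the collision cell. When an
acquisition does not encode the collision energy per scan,
`msio.read_mzml(..., ce_cycle=[0, 10, 20, 40])` assigns energies by MS2
scan index modulo the cycle.

## Feature curation

**Deisotoping.** Isotopologue series are consolidated onto their
monoisotopic member. Spacing constant 1.003355 Da (¹³C−¹²C) divided by
charge; charges 1–3 tried per cluster seed, the charge collecting the
most consecutive members winning (ties to the lower charge); m/z
tolerance 10 ppm; coelution window ±0.05 min; at most 3 isotopologues
above the monoisotopic peak. Seeding is greedy in descending intensity
(ties to ascending m/z) and a feature joins at most one cluster, which
makes the operation deterministic and idempotent. A non-decreasing
intensity envelope (unusual for small molecules) is logged but not
enforced, since no abundance model is assumed.

**Adduct grouping.** Two coeluting features are linked when their m/z
difference matches the difference of two adduct offsets of their
polarity within the ppm tolerance; groups are connected components of
that relation. Shipped offsets (mass added to the neutral molecule,
singly charged): +1.007276 ([M+H]⁺), +22.989218 ([M+Na]⁺), +18.033823
([M+NH₄]⁺), +38.963158 ([M+K]⁺), −1.007276 ([M−H]⁻), +44.998201
([M+HCOO]⁻); the table is editable configuration. The most intense
member is retained as the representative precursor (maximizing
downstream MRM sensitivity); non-redundant adducts pass through as
independent precursors. Adducts are deliberately *not* collapsed to a
neutral mass by default — for many polar metabolites an adduct is the
dominant or only observable precursor.

**In-source fragment (ISF) filter.** A feature F is classified
ISF-derived only when all three criteria hold against some candidate
parent P:

1. *accurate-mass association* — P's MS/MS contains a peak matching F's
   m/z within `ppm` (default 10; the useful range is 5–10);
2. *coelution* — |RT(F) − RT(P)| ≤ `rt_window_min` (default 0.05);
3. *collision-energy dependence* — that peak is detected in P's 0 eV
   spectrum and its maximum over the 10/20/40 eV spectra is at least
   `persistence_factor` (default 0.5) of the 0 eV intensity.

The persistence factor operationalizes "persists or increases at higher
energy": 0.5 tolerates sampling variation while rejecting species that
collapse immediately, and is configurable. Parent candidates must exceed
F's m/z by `parent_min_mass_gap_da` (default 2.0 — a fragment cannot
outweigh its parent) and carry at least 10% of F's intensity (so a trace
feature is never assigned as the "parent" of a dominant one). With
several qualifying parents the recorded assignment names the one with
the smallest ppm error (ties to smallest |ΔRT|); the verdict is
unchanged. Widening either tolerance can only grow the removed set
(monotonicity, property-tested). The pipeline order is fixed:
deisotope → adduct grouping → ISF filter.

## Fragment tracking

Each retained precursor is associated with at most one MS/MS spectrum
per energy (10 ppm / ±0.05 min matching; duplicate energies resolve to
the highest TIC; precursors without any MS/MS are dropped and counted —
DDA coverage reporting). Per energy the top 10 fragment peaks enter
tracking after excluding everything within 2.0 Da of the precursor, so
unfragmented precursor survival can never become a transition. Peaks are
grouped across energies in descending intensity order against
intensity-weighted group centroids with a ±0.5 Da tolerance; a peak
joins the nearest centroid that lacks an observation at its energy,
otherwise it seeds a new group. Centroid (rather than first-member)
comparison prevents chaining drift, and the intensity-sorted order makes
grouping invariant to peak permutation. A missing energy is recorded as
absent, not zero — in DDA, absence may reflect sampling, not a true zero.

A profile observed at ≥3 energies is flagged *irregular* when, ordered
by energy, it falls below 10% of its maximum (after previously having
been above that level) and later rebounds above 50% — a discontinuity
that disqualifies a fragment from quantifier candidacy. The 0.1/0.5
thresholds are package choices for the qualitative notion of
non-reproducible behavior, and both are configurable. Sparser profiles
skip the rule and are handled by the fallback below.

## Collision-energy optimization

Profiles with ≥3 observed energies are fit with a univariate
interpolating spline — smoothing 0, i.e. the curve passes through every
observed point (`scipy.interpolate.InterpolatedUnivariateSpline`).
The default degree is 2 (quadratic; three points still admit the fit),
with cubic selectable. The optimal CE is the argmax of the fitted curve
over the observed span, located on a 0.1 eV grid and refined by bounded
scalar maximization in the bracketing cell; extrapolated spline
excursions outside the sampled span are never trusted. Predictions below
5 eV — the lower operational limit of standard triple quadrupoles — are
clamped to 5 eV and labelled `clamped_floor`. Profiles observed at one
or two energies fall back to the observed energy of maximal intensity,
clamped to the same floor, so sparse fragments still yield a usable
transition. Intensities are fit on the raw scale (no log transform). A
hook (`SplineConfig.ce_adjust_fn`) accepts a user-supplied CE adjustment
applied before clamping, e.g. an externally trained refinement model.

Numerical guarantees, asserted by tests: interpolation residuals are
zero to 1e−6 relative; the argmax agrees with an independent 0.01 eV
brute-force grid search within 0.1 eV over 1,000 random 3–4-point
profiles; all emitted energies lie in [5, 40] eV.

## Transition selection and method assembly

The quantifier is the most intense *stable* fragment — spline-eligible
(≥3 energies) and not irregular — ranked by predicted maximum intensity,
ties broken by more observed energies, then lower fragment m/z.
Qualifiers are the next `n_qualifiers` (default 1) in the same ranking.
Every transition keeps ≥2.0 Da separation from its precursor (with 1 nDa
numerical slack so the boundary decision is free of float round-off).
When only fallback profiles exist the compound emits a single quantifier
transition, flagged as such; when nothing usable remains it is dropped
with a diagnostic. In reference-guided mode, a reference quantifier
fragment matching an observed group within ±0.5 Da is promoted to the
quantifier slot while its collision energy is taken from the empirical
model, never from the reference.

Transitions from multiple experimental sets merge by union; duplicates
(same polarity, precursor within 10 ppm, quantifier fragment within
±0.5 Da, RT within the scheduling window) collapse to the instance with
the higher predicted quantifier intensity. Scheduling uses ±0.3 min
windows around the pooled-sample retention time and a 500 ms cycle time;
polarity switching is enabled automatically when both modes are present.
The exported CSV (`compound, precursor_mz, fragment_mz, polarity, ce_ev,
rt_min, rt_window_min, role, peak_area`) prints m/z at 4 decimals, RT at
2 and CE at 1 — method-editor precision — and round-trips exactly at
that precision. A dynamic-MRM variant adds explicit start/stop RT
columns (start clamped at zero), and expected qualifier/quantifier
intensity ratios are exported as JSON metadata. For closing the loop on
synthetic acquisitions, `umrm.quant.trapezoidal_peak_area` integrates a
transition chromatogram over its scheduling window; it deliberately has
no baseline model or peak-shape fit and is not a substitute for vendor
peak integration of real data.

## Synthetic data generator

`GeneratorSpec` defaults describe a realistic mid-size pooled run:
100 compounds (neutral mass 150–800 Da, RT 1–14 min, abundance
10⁵–10⁷), an ISF load of 0.6 per compound, two isotopologues per
monoisotopic feature with a geometric envelope (ratios 0.2/0.04), a 30%
chance of one extra adduct at 10–50% of base intensity, and 3–6
fragments per compound. Fragment CE responses are scaled Gaussians with
peak location μ ∈ [5, 38] eV and width σ ∈ [5, 15] eV, evaluated at the
four sampled energies; a sigmoid-decay family places true optima at
0 eV to exercise the clamping rule. Fragment amplitudes follow a steep
geometric ladder (leading fraction 0.6 of abundance, ratio 0.4, ±10%
jitter), emulating MS/MS dynamic range while keeping intensity ranks
well separated. ISF-parent compounds carry one source-labile fragment
(μ ∈ [8, 18], σ ∈ [8, 15] eV) whose 0 eV response is guaranteed above
the recording floor; the planted ISF feature mirrors it and coelutes
with the parent within ±0.02 min. The noise model is multiplicative
log-normal on intensities (σ = 0.10), Gaussian m/z jitter (3 ppm) and
Gaussian RT jitter (0.01 min); `GeneratorSpec.noiseless()` zeroes all
three. Runs are byte-identical under a fixed seed, and the manifest
fully reconstructs expectations; the analytic argmax of each planted
response curve is the oracle for CE recovery.

Two deliberate design points keep the planted truth unambiguous. First,
fragment m/z are drawn after all precursor (m/z, RT) pairs and rejected
within 0.05 Da of any coeluting precursor or of its adduct-delta and
isotope-offset relatives — otherwise rare mass coincidences would make a
genuine precursor legitimately classifiable as an in-source fragment,
and "planted truth" would stop being truth. Second, the ground-truth
quantifier is defined by the maximum response *over the sampled
energies* among fragments detectable at ≥3 of them: with response
widths near the 5 eV minimum, the 0/10/20/40 eV grid attenuates mid-gap
peaks by up to ~7×, so sampled and continuous intensity orderings can
genuinely diverge and rank agreement is only well-defined at the
sampling resolution. The quantifier-identity validation therefore uses
widths ≥ 8 eV, where the ranking is resolvable (verified exact over many
seeds).

What the generator does not emulate: chromatographic peak shapes
(features are point events with an RT), chimeric MS/MS from co-isolated
precursors, elemental-composition isotope patterns, charge states above
1 in the planted data, and matrix-dependent ionization effects. Passing
tests therefore demonstrate the correctness of the curation, modeling
and selection logic under the stated acquisition model — not robustness
to every artifact of real chromatography.

## Problem sizes and validation summary

The test suite validates on runs of 15–100 compounds with ISF loads of
0.4–0.6 and on 500–1,000 randomly drawn fragment profiles; these sizes
fully exercise every rule while keeping the suite fast. On noiseless
100-compound runs the pipeline recovers all planted precursors, removes
all planted ISFs, and selects the planted quantifier for every compound
(under the rank-resolvable fixture above); with the default noise model
planted-ISF recall stays ≥ 0.9 and median |ΔCE| against the analytic
response-curve optimum is well under 2 eV. End-to-end outputs are
byte-identical across repeat runs, and stage counts are non-increasing
through curation — mirroring the characteristic accounting pattern in
which isotope consolidation trims modestly while ISF removal takes out
the bulk of MS/MS-bearing redundancy.

## Known limitations

- The basic MS1 feature extractor (`detect_features_from_ms1`) is a
  greedy apex picker intended for centroid survey scans and synthetic
  data; real profile-mode chromatograms deserve a dedicated peak picker
  upstream.
- ISF filtering is evidence-based, not mechanistic: a true precursor
  that coelutes with a higher-mass compound *and* matches one of its
  low-energy fragment masses within tolerance is indistinguishable from
  an in-source fragment by these criteria alone.
- Quantifier/qualifier intensity ranking inherits the resolution of the
  4-point energy grid; near-tied fragments with narrow CE responses may
  rank differently than their true continuous response curves would.
- The quantifier/qualifier transition-ratio check on acquired QqQ data
  is exported as metadata only; ratio-based QC of acquisition output is
  reporting, not a gate.
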