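# umrm

Convert untargeted LC–MS/MS discovery data into scheduled
triple-quadrupole MRM methods.

Targeted quantitation by multiple reaction monitoring (MRM) is sensitive
and reproducible but traditionally needs precursor→fragment transitions
defined in advance, which locks it out of discovery-driven metabolomics
and lipidomics. `umrm` closes that gap: it takes a pooled-sample
high-resolution MS1 feature table together with data-dependent MS/MS
spectra acquired at stepped collision energies (0, 10, 20 and 40 eV) and
turns them into a curated, collision-energy-optimized,
retention-time-scheduled transition table that a triple-quadrupole
method editor can ingest directly.

The workflow, stage by stage:

1. **Isotope consolidation** — isotopologue series (spacing
   1.003355/z Da, coeluting) collapse onto their monoisotopic feature.
2. **Adduct grouping** — coeluting features whose m/z differences match
   charge-carrier offsets ([M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M+K]⁺; [M−H]⁻,
   [M+HCOO]⁻) are grouped and one representative precursor kept per
   group. Adducts are treated as analytically valid precursors — only
   *redundant* forms of the same molecule are merged.
3. **In-source fragment (ISF) filtering** — a feature is removed as
   fragment-derived only when three criteria converge on a coeluting
   higher-mass parent: accurate-mass match of a parent MS/MS fragment
   (≤10 ppm), chromatographic coelution (±0.05 min), and detection in
   the parent's 0 eV spectrum that persists or grows at higher energy.
   Every removal is justified by a recorded assignment.
4. **Fragment tracking** — per precursor, the top-10 fragment peaks per
   energy are tracked across energies with a ±0.5 Da grouping tolerance
   (intensity-weighted centroids), giving one collision-energy–intensity
   profile per recurring fragment. Fragments within 2.0 Da of the
   precursor are excluded; profiles that collapse and rebound across
   energies are flagged irregular.
5. **Collision-energy optimization** — each profile observed at ≥3
   energies is fit with an interpolating spline (smoothing 0, degree 2
   by default); the optimal CE is the spline argmax over the sampled
   span, clamped to the 5 eV instrument floor. Sparser profiles fall
   back to the observed energy of maximal intensity.
6. **Transition selection and scheduling** — the quantifier is the most
   intense stable fragment, qualifiers the next in rank; all transitions
   keep ≥2.0 Da separation from the precursor and CEs in [5, 40] eV.
   Transitions merge across experimental sets into one dynamic-MRM
   method with ±0.3 min windows and a 500 ms cycle time, with polarity
   switching when both modes are present.

A synthetic-data generator (`umrm.synth_fixtures`) emulates the full
acquisition — isotope envelopes, adduct series, coeluting in-source
fragments mirroring 0 eV MS/MS peaks, and per-fragment Gaussian
CE-response curves sampled at the four energies with configurable
noise — and every run carries a ground-truth manifest, so each pipeline
stage is validated end to end without any external data.

## Worked example

Simulate a 25-compound pooled run with a 0.6 ISF load and build a method
from it:

```sh
umrm simulate --compounds 25 --isf-fraction 0.6 --seed 11 -o demo/sim
# wrote 108 features, 108 spectra: demo/sim/features.csv, demo/sim/run.mzml, demo/sim/manifest.json

umrm build --features demo/sim/features.csv --ms2 demo/sim/run.mzml -o demo/out
# wrote 49 transitions for 25 compounds to demo/out/transitions.csv
```

`demo/out/stage_counts.json` records the curation accounting:

```json
{
 "features_total": 108,
 "features_with_ms2": 25,
 "after_isotope_consolidation": 47,
 "after_adduct_grouping": 41,
 "after_isf_removal": 28,
 "compounds_emitted": 25
}
```

108 raw features (25 monoisotopic precursors plus their isotopologues,
adducts and 15 planted in-source fragments) shrink modestly at isotope
consolidation and sharply at ISF removal — the characteristic signature
of in-source fragmentation dominating MS1 redundancy. The transition
table starts:

```
compound,precursor_mz,fragment_mz,polarity,ce_ev,rt_min,rt_window_min,role,peak_area
211.3924@1.24,211.3924,60.2772,positive,13.1,1.24,0.30,quantifier,
211.3924@1.24,211.3924,179.8326,positive,23.5,1.24,0.30,qualifier,
292.1554@1.43,292.1554,238.2736,positive,20.0,1.43,0.30,quantifier,
```

Each compound gets one quantifier and (where a second reproducible
fragment exists) one qualifier, with its spline-optimized collision
energy and a ±0.30 min scheduling window around the pooled-sample
retention time. Alongside the main table, `build` writes
`dynamic_mrm.csv` (the same transitions with explicit start/stop RT
columns for method editors that want them), `transition_ratios.json`
(expected qualifier/quantifier intensity ratios, for downstream
transition-ratio consistency checks), a `config.yaml` snapshot and a
run log.

`umrm bench predicted.csv reference.csv` compares two transition tables:
fragment m/z agreement within ±0.5 Da, the ΔCE distribution of matched
quantifiers (median ΔCE for directional bias, median |ΔCE| for typical
magnitude, fractions within ±5 and ±10 eV), and quantifier/qualifier
overlap. `umrm validate` schema-checks any table, and a reference
transition CSV passed to `umrm build --reference` enables
reference-guided mode, where validated fragment assignments seed
quantifier choice while collision energies stay empirically modeled.

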