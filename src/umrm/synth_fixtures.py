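"""Synthetic pooled-sample runs with full ground truth.

Emulates the discovery acquisition the pipeline consumes: an MS1 feature
table containing monoisotopic features, isotopologue envelopes, adduct
series, and coeluting in-source-fragment (ISF) features, together with a
stepped-energy DDA mzML carrying one MS/MS spectrum per (precursor,
collision energy) at 0/10/20/40 eV.  Fragment intensities follow planted
collision-energy response curves (scaled Gaussians by default, with peak
location μ and width σ drawn per fragment; a sigmoid-decay family places
true optima at 0 eV to exercise the 5 eV clamping rule).  ISF features
coelute with their parent within ±0.02 min and mirror a fragment present
in the parent's 0 eV spectrum.

Every run is fully determined by its seed and spec; the ground-truth
manifest reconstructs all expectations, and the continuous response
curve's analytic argmax is the oracle for collision-energy recovery.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import msio
from .benchmark import delta_ce_summary
from .config import DEFAULT_ADDUCT_DELTAS, ISOTOPE_SPACING_DA
from .records import (
    NEGATIVE,
    POSITIVE,
    SAMPLED_ENERGIES,
    FeatureRecord,
    SpectrumRecord,
)

GAUSSIAN = "gaussian"
SIGMOID_DECAY = "sigmoid_decay"


@dataclass
class GeneratorSpec:
    """Composition and noise model of one synthetic pooled-sample run.

    Defaults represent a realistic mid-size discovery run: 100 compounds,
    an ISF load of 0.6 features per compound (within the range implied by
    heavy in-source fragmentation of real matrices), two isotopologues per
    monoisotopic feature with a geometric envelope, ~10% multiplicative
    intensity noise, 3 ppm mass jitter, and 0.01 min RT jitter.
    """

    n_compounds: int = 100
    isf_fraction: float = 0.6
    isotope_depth: int = 2
    isotope_ratios: tuple[float, ...] = (0.2, 0.04)
    adduct_fraction: float = 0.3
    fragments_min: int = 3
    fragments_max: int = 6
    polarity: str = POSITIVE
    neutral_mass_range: tuple[float, float] = (150.0, 800.0)
    rt_range_min: tuple[float, float] = (1.0, 14.0)
    log10_abundance_range: tuple[float, float] = (5.0, 7.0)
    #: per-fragment response peak location (eV) and width (eV) ranges
    mu_range_ev: tuple[float, float] = (5.0, 38.0)
    sigma_range_ev: tuple[float, float] = (5.0, 15.0)
    response_family: str = GAUSSIAN
    #: leading fragment amplitude as a fraction of compound abundance, and
    #: the geometric ratio between successive fragment ranks.  The steep
    #: ladder emulates the dynamic range of real MS/MS spectra and keeps
    #: fragment intensity ranks unambiguous.
    amplitude_fraction: float = 0.6
    amplitude_ratio: float = 0.4
    # noise model
    intensity_cv: float = 0.10       # log-normal sigma on intensities
    mz_jitter_ppm: float = 3.0       # gaussian m/z jitter
    rt_jitter_min: float = 0.01      # gaussian RT jitter
    ms2_floor: float = 1.0           # peaks below this are not recorded
    n_ms1_scans: int = 8

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")
        if not 0.0 <= self.isf_fraction <= 1.0:
            raise ValueError("isf_fraction must lie in [0, 1]")
        if self.fragments_min < 1 or self.fragments_max < self.fragments_min:
            raise ValueError("invalid fragment count range")
        if self.isotope_depth > len(self.isotope_ratios):
            raise ValueError("isotope_depth exceeds the supplied isotope_ratios")
        if self.response_family not in (GAUSSIAN, SIGMOID_DECAY):
            raise ValueError(f"unknown response family {self.response_family!r}")

    @classmethod
    def noiseless(cls, **kwargs) -> "GeneratorSpec":
        """A spec with all noise terms zeroed (planted values exact)."""
        kwargs.setdefault("intensity_cv", 0.0)
        kwargs.setdefault("mz_jitter_ppm", 0.0)
        kwargs.setdefault("rt_jitter_min", 0.0)
        return cls(**kwargs)


@dataclass
class TrueFragment:
    """A planted fragment with its CE–intensity response curve."""

    mz: float
    amplitude: float
    family: str
    mu_ev: float
    sigma_ev: float

    def response(self, ce: float) -> float:
        if self.family == GAUSSIAN:
            return self.amplitude * math.exp(-((ce - self.mu_ev) ** 2) / (2 * self.sigma_ev**2))
        # sigmoid decay: maximal at 0 eV, falls off around mu with width sigma
        return self.amplitude / (1.0 + math.exp((ce - self.mu_ev) / self.sigma_ev))

    def optimal_ce(self, floor: float = 5.0, ceiling: float = 40.0) -> float:
        """Analytic argmax of the continuous response, clamped to [floor, ceiling]."""
        peak = self.mu_ev if self.family == GAUSSIAN else 0.0
        return min(max(peak, floor), ceiling)


@dataclass
class TrueCompound:
    compound_id: str
    neutral_mass: float
    rt_min: float
    abundance: float
    polarity: str
    adducts: list[tuple[str, float, float]]  # (label, mz, intensity)
    fragments: list[TrueFragment]
    base_feature_id: str = ""

    @property
    def base_mz(self) -> float:
        return self.adducts[0][1]

    def stable_fragments(self, floor: float = 1.0, min_energies: int = 3) -> list[TrueFragment]:
        """Fragments detectable at >= ``min_energies`` sampled energies."""
        return [
            f
            for f in self.fragments
            if sum(f.response(ce) >= floor for ce in SAMPLED_ENERGIES) >= min_energies
        ]

    def quantifier_fragment(self, floor: float = 1.0) -> TrueFragment:
        """The planted most-intense stable fragment.

        "Most intense" is evaluated at the sampled energies — the profile
        the workflow actually observes — and "stable" mirrors the
        selection rule: detectable at three or more sampled energies
        given the recording floor.  If no fragment qualifies, the overall
        most intense fragment is returned (sparse-coverage fallback).
        """
        cands = self.stable_fragments(floor) or self.fragments
        return max(
            cands, key=lambda f: max(f.response(ce) for ce in SAMPLED_ENERGIES)
        )


@dataclass
class GroundTruth:
    """Planted composition of a synthetic run; fully determines the files."""

    seed: int
    compounds: list[TrueCompound]
    planted_isotopes: list[str] = field(default_factory=list)   # feature ids
    planted_adduct_features: list[str] = field(default_factory=list)
    planted_isfs: list[tuple[str, str, float]] = field(default_factory=list)
    # (feature_id, parent_compound_id, mirrored fragment mz)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        compounds = []
        for c in d["compounds"]:
            frags = [TrueFragment(**f) for f in c.pop("fragments")]
            adducts = [tuple(a) for a in c.pop("adducts")]
            compounds.append(TrueCompound(fragments=frags, adducts=adducts, **c))
        return cls(
            seed=d["seed"],
            compounds=compounds,
            planted_isotopes=list(d["planted_isotopes"]),
            planted_adduct_features=list(d["planted_adduct_features"]),
            planted_isfs=[tuple(x) for x in d["planted_isfs"]],
        )


@dataclass
class SyntheticRun:
    features: list[FeatureRecord]
    spectra: list[SpectrumRecord]
    truth: GroundTruth
    feature_table_path: Optional[Path] = None
    mzml_path: Optional[Path] = None
    manifest_path: Optional[Path] = None


def _draw_fragment_mzs(
    rng: np.random.Generator,
    k: int,
    base_mz: float,
    forbidden: list[float],
    min_gap_da: float = 0.05,
) -> list[float]:
    """Fragment m/z values below the precursor, mutually >3 Da apart.

    ``forbidden`` lists precursor m/z values of coeluting compounds; a
    candidate within ``min_gap_da`` of one is redrawn so that a planted
    fragment never masquerades as another compound's intact precursor
    by mass coincidence — the ground truth stays unambiguous.
    """
    mzs: list[float] = []
    hi = base_mz - 20.0
    forbidden_arr = np.asarray(forbidden) if forbidden else np.empty(0)
    while len(mzs) < k:
        cand = float(rng.uniform(50.0, hi))
        if all(abs(cand - m) > 3.0 for m in mzs) and (
            forbidden_arr.size == 0
            or float(np.min(np.abs(forbidden_arr - cand))) > min_gap_da
        ):
            mzs.append(cand)
    return mzs


def _collision_offsets(polarity: str) -> np.ndarray:
    """Mass offsets at which a feature can be mistaken for a curation
    relative (adduct partner or isotopologue) of a coeluting precursor.

    Used to keep planted fragments/ISFs from forming accidental adduct or
    isotope relationships with other compounds' precursor features.
    """
    deltas = [d for d, pol in DEFAULT_ADDUCT_DELTAS.values() if pol == polarity]
    pair = [db - da for da in deltas for db in deltas]
    offsets = set(pair)
    offsets.update(a + b for a in pair for b in pair)
    for z in (1, 2, 3):
        for kk in (1, 2, 3):
            offsets.add(-kk * ISOTOPE_SPACING_DA / z)
            offsets.add(kk * ISOTOPE_SPACING_DA / z)
    return np.array(sorted(offsets))


def generate_run(
    spec: GeneratorSpec, seed: int, outdir: Optional[Path] = None
) -> SyntheticRun:
    """Generate one synthetic run; optionally write its three files.

    When ``outdir`` is given, writes ``features.csv``, ``run.mzml`` and
    ``manifest.json``; regeneration with the same spec and seed is
    byte-identical.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    adduct_labels = {
        POSITIVE: ["[M+H]+", "[M+Na]+", "[M+NH4]+"],
        NEGATIVE: ["[M-H]-", "[M+HCOO]-"],
    }[spec.polarity]

    def jitter_mz(mz: float) -> float:
        if spec.mz_jitter_ppm <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm) * 1e-6)

    def jitter_rt(rt: float) -> float:
        if spec.rt_jitter_min <= 0:
            return max(rt, 0.0)
        return max(rt + float(rng.normal(0.0, spec.rt_jitter_min)), 0.0)

    def jitter_intensity(i: float) -> float:
        if spec.intensity_cv <= 0:
            return i
        return i * float(np.exp(rng.normal(0.0, spec.intensity_cv)))

    n_isf = int(round(spec.isf_fraction * spec.n_compounds))
    isf_parent_idx = set(
        rng.choice(spec.n_compounds, size=n_isf, replace=False).tolist()
    ) if n_isf else set()

    compounds: list[TrueCompound] = []
    features: list[FeatureRecord] = []
    spectra: list[SpectrumRecord] = []
    truth = GroundTruth(seed=seed, compounds=compounds)
    fid = 0

    def next_fid(tag: str) -> str:
        nonlocal fid
        fid += 1
        return f"{tag}{fid:05d}"

    # draw all precursor identities first so fragment m/z can avoid
    # colliding with coeluting precursors (unambiguous ground truth)
    base_label = adduct_labels[0]
    base_props = []
    for _ in range(spec.n_compounds):
        neutral = float(rng.uniform(*spec.neutral_mass_range))
        rt = float(rng.uniform(*spec.rt_range_min))
        abundance = float(10 ** rng.uniform(*spec.log10_abundance_range))
        base_props.append((neutral, rt, abundance))

    for ci in range(spec.n_compounds):
        neutral, rt, abundance = base_props[ci]
        base_mz = neutral + DEFAULT_ADDUCT_DELTAS[base_label][0]

        offsets = _collision_offsets(spec.polarity)
        forbidden = [
            n2 + DEFAULT_ADDUCT_DELTAS[base_label][0] + off
            for j, (n2, rt2, _) in enumerate(base_props)
            if j != ci and abs(rt2 - rt) <= 0.2
            for off in offsets
        ]
        k = int(rng.integers(spec.fragments_min, spec.fragments_max + 1))
        frag_mzs = _draw_fragment_mzs(rng, k, base_mz, forbidden)
        fragments: list[TrueFragment] = []
        for j, fmz in enumerate(frag_mzs):
            amp = abundance * spec.amplitude_fraction * spec.amplitude_ratio**j
            amp *= float(rng.uniform(0.9, 1.1))
            if ci in isf_parent_idx and j == 0:
                # the source-labile fragment mirrored by the planted ISF:
                # substantial 0 eV response guarantees the low-energy signature
                mu = float(rng.uniform(8.0, 18.0))
                sigma = float(rng.uniform(8.0, 15.0))
            else:
                mu = float(rng.uniform(*spec.mu_range_ev))
                sigma = float(rng.uniform(*spec.sigma_range_ev))
            if spec.response_family == SIGMOID_DECAY:
                mu = float(rng.uniform(5.0, 25.0))
            fragments.append(
                TrueFragment(mz=fmz, amplitude=amp, family=spec.response_family,
                             mu_ev=mu, sigma_ev=sigma)
            )

        adducts: list[tuple[str, float, float]] = [(base_label, base_mz, abundance)]
        if rng.uniform() < spec.adduct_fraction and len(adduct_labels) > 1:
            extra = adduct_labels[int(rng.integers(1, len(adduct_labels)))]
            adducts.append(
                (extra, neutral + DEFAULT_ADDUCT_DELTAS[extra][0],
                 abundance * float(rng.uniform(0.1, 0.5)))
            )

        comp = TrueCompound(
            compound_id=f"C{ci:04d}",
            neutral_mass=neutral,
            rt_min=rt,
            abundance=abundance,
            polarity=spec.polarity,
            adducts=adducts,
            fragments=fragments,
        )

        # MS1 features: monoisotopic adducts plus isotopologue envelopes
        for ai, (label, amz, ainten) in enumerate(adducts):
            f = FeatureRecord(
                feature_id=next_fid("F"),
                mz=jitter_mz(amz),
                rt_min=jitter_rt(rt),
                intensity=jitter_intensity(ainten),
                polarity=spec.polarity,
            )
            features.append(f)
            if ai == 0:
                comp.base_feature_id = f.feature_id
            for d in range(spec.isotope_depth):
                iso = FeatureRecord(
                    feature_id=next_fid("I"),
                    mz=jitter_mz(amz + (d + 1) * ISOTOPE_SPACING_DA),
                    rt_min=jitter_rt(rt),
                    intensity=jitter_intensity(ainten * spec.isotope_ratios[d]),
                    polarity=spec.polarity,
                )
                features.append(iso)
                truth.planted_isotopes.append(iso.feature_id)
            if ai > 0:
                truth.planted_adduct_features.append(f.feature_id)

        # stepped-energy MS/MS on the base precursor
        for ce in SAMPLED_ENERGIES:
            peaks = []
            for frag in fragments:
                inten = jitter_intensity(frag.response(ce))
                if inten >= spec.ms2_floor:
                    peaks.append((jitter_mz(frag.mz), inten))
            # unfragmented precursor survival, decaying with energy
            survival = abundance * 0.8 / (1.0 + math.exp((ce - 15.0) / 6.0))
            if survival >= spec.ms2_floor:
                peaks.append((jitter_mz(base_mz), jitter_intensity(survival)))
            spectra.append(
                SpectrumRecord(
                    scan_id="",  # assigned after RT sort
                    ms_level=2,
                    rt_min=jitter_rt(rt),
                    polarity=spec.polarity,
                    peaks=peaks,
                    precursor_mz=jitter_mz(base_mz),
                    collision_energy_ev=ce,
                )
            )
        compounds.append(comp)

    # planted in-source fragments mirroring the parents' labile fragment
    for ci in sorted(isf_parent_idx):
        comp = compounds[ci]
        frag = comp.fragments[0]
        isf = FeatureRecord(
            feature_id=next_fid("S"),
            mz=jitter_mz(frag.mz),
            rt_min=jitter_rt(comp.rt_min + float(rng.uniform(-0.02, 0.02))),
            intensity=jitter_intensity(comp.abundance * float(rng.uniform(0.05, 0.3))),
            polarity=spec.polarity,
        )
        features.append(isf)
        truth.planted_isfs.append((isf.feature_id, comp.compound_id, frag.mz))

    # MS1 survey scans containing nearby feature peaks (for mzML round-trips)
    if spec.n_compounds and spec.n_ms1_scans:
        lo, hi = spec.rt_range_min
        for srt in np.linspace(lo, hi, spec.n_ms1_scans):
            peaks = [
                (f.mz, f.intensity)
                for f in features
                if abs(f.rt_min - srt) <= (hi - lo) / (2 * spec.n_ms1_scans)
            ]
            spectra.append(
                SpectrumRecord(
                    scan_id="",
                    ms_level=1,
                    rt_min=float(srt),
                    polarity=spec.polarity,
                    peaks=peaks,
                )
            )

    spectra.sort(key=lambda s: (s.rt_min, s.ms_level, s.collision_energy_ev or 0.0))
    for i, sp in enumerate(spectra):
        sp.scan_id = f"scan={i + 1}"
    features.sort(key=lambda f: (f.rt_min, f.mz))

    run = SyntheticRun(features=features, spectra=spectra, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        run.feature_table_path = outdir / "features.csv"
        run.mzml_path = outdir / "run.mzml"
        run.manifest_path = outdir / "manifest.json"
        msio.write_feature_table(features, run.feature_table_path)
        msio.write_mzml(spectra, run.mzml_path)
        run.manifest_path.write_text(truth.to_json(), encoding="utf-8")
    return run


def score_against_truth(result, truth: GroundTruth, fragment_tol_da: float = 0.5) -> dict:
    """Score a pipeline result against the planted ground truth.

    ``result`` is the object returned by the pipeline run on the same
    synthetic files (retained features, ISF-stage assignments, and the
    final method).  Reports ISF recall/precision, true-precursor
    retention, fragment m/z agreement within ±0.5 Da, quantifier identity
    rate, and the ΔCE distribution of emitted collision energies against
    the analytic argmax of each planted response curve.
    """
    retained_ids = {f.feature_id for f in result.retained_features}
    planted_isf_ids = {fid for fid, _, _ in truth.planted_isfs}

    n_isf = len(planted_isf_ids)
    n_removed = sum(1 for fid in planted_isf_ids if fid not in retained_ids)
    isf_recall = n_removed / n_isf if n_isf else float("nan")

    removed_by_filter = {a.fragment_feature.feature_id for a in result.isf_assignments}
    isf_precision = (
        len(removed_by_filter & planted_isf_ids) / len(removed_by_filter)
        if removed_by_filter
        else float("nan")
    )

    base_ids = {c.base_feature_id: c for c in truth.compounds}
    n_true = len(base_ids)
    n_retained_true = sum(1 for fid in base_ids if fid in retained_ids)
    retention_rate = n_retained_true / n_true if n_true else float("nan")
    false_removals = [fid for fid in base_ids if fid not in retained_ids]

    # match emitted compounds to planted compounds by base-feature identity
    deltas: list[float] = []
    n_frag = 0
    n_frag_matched = 0
    n_quant = 0
    n_quant_identity = 0
    for comp in result.method.compounds:
        tc = base_ids.get(comp.precursor.feature_id)
        if tc is None:
            continue
        preds = [(comp.quantifier, True)] + [(q, False) for q in comp.qualifiers]
        for pred, is_quant in preds:
            n_frag += 1
            fmz = pred.profile.fragment.group_mz
            matches = [f for f in tc.fragments if abs(f.mz - fmz) <= fragment_tol_da]
            if not matches:
                continue
            n_frag_matched += 1
            planted = min(matches, key=lambda f: abs(f.mz - fmz))
            deltas.append(pred.ce_opt_ev - planted.optimal_ce())
            if is_quant:
                n_quant += 1
                if abs(tc.quantifier_fragment().mz - fmz) <= fragment_tol_da:
                    n_quant_identity += 1

    return {
        "isf_recall": isf_recall,
        "isf_removed": n_removed,
        "isf_planted": n_isf,
        "isf_precision": isf_precision,
        "precursor_retention_rate": retention_rate,
        "true_precursors": n_true,
        "true_precursors_retained": n_retained_true,
        "false_removals": false_removals,
        "fragment_match_rate": (n_frag_matched / n_frag) if n_frag else float("nan"),
        "quantifier_identity_rate": (
            n_quant_identity / n_quant if n_quant else float("nan")
        ),
        "ce_summary": delta_ce_summary(deltas),
    }


def generate_adversarial_proximity_set(
    n_compounds: int = 8, seed: int = 0, polarity: str = POSITIVE
) -> list:
    """Spectrum sets whose dominant fragments crowd the precursor m/z.

    Each compound's MS/MS (at 10/20/40 eV, a reproducible three-energy
    profile) contains candidate fragments 1.0, 1.5, 1.9, 2.0 and 3.0 Da
    below the precursor, with the sub-2.0 Da peaks the most intense — so
    any leak past the precursor-separation rule would immediately be
    selected as quantifier.  Used to stress transition selection.
    """
    from .fragment_profiles import PrecursorSpectrumSet

    rng = np.random.default_rng(seed)
    shape = {10.0: 0.6, 20.0: 1.0, 40.0: 0.3}
    offsets = [(1.0, 10000.0), (1.5, 9000.0), (1.9, 8000.0), (2.0, 5000.0), (3.0, 2500.0)]
    sets = []
    for i in range(n_compounds):
        pmz = float(rng.uniform(300.0, 700.0))
        rt = float(rng.uniform(1.0, 14.0))
        prec = FeatureRecord(
            feature_id=f"ADV{i:03d}", mz=pmz, rt_min=rt, intensity=1e6, polarity=polarity
        )
        spectra = {
            ce: SpectrumRecord(
                scan_id=f"adv{i}_{int(ce)}",
                ms_level=2,
                rt_min=rt,
                polarity=polarity,
                peaks=[(pmz - off, amp * frac) for off, amp in offsets],
                precursor_mz=pmz,
                collision_energy_ev=ce,
            )
            for ce, frac in shape.items()
        }
        sets.append(PrecursorSpectrumSet(precursor=prec, spectra=spectra))
    return sets
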