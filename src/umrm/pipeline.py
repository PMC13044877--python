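"""End-to-end orchestration: features + stepped-energy MS/MS → MRM method.

Stage order: isotope consolidation → adduct grouping → in-source-fragment
filtering → precursor–spectrum association → cross-energy fragment
tracking → collision-energy optimization → quantifier/qualifier selection
→ scheduled method assembly.  Per-stage feature counts are reported in
the curation accounting convention (features, features with MS/MS, after
isotope consolidation, after ISF removal) and are non-increasing through
the curation stages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import feature_curation, fragment_profiles, isf_filter, transition_builder
from .ce_optimizer import predict_ce
from .config import RunConfig
from .feature_curation import AdductGroup, IsotopeCluster
from .fragment_profiles import PrecursorSpectrumSet
from .isf_filter import ISFAssignment
from .records import FeatureRecord, SpectrumRecord, TransitionRow
from .transition_builder import CompoundTransitions, MRMMethod

log = logging.getLogger(__name__)


@dataclass
class StageCounts:
    """Feature accounting through the curation stages."""

    features_total: int = 0
    features_with_ms2: int = 0
    after_isotope_consolidation: int = 0
    after_adduct_grouping: int = 0
    after_isf_removal: int = 0
    compounds_emitted: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def non_increasing(self) -> bool:
        seq = [
            self.features_total,
            self.after_isotope_consolidation,
            self.after_adduct_grouping,
            self.after_isf_removal,
        ]
        return all(a >= b for a, b in zip(seq, seq[1:]))


@dataclass
class PipelineResult:
    curated_features: list[FeatureRecord]
    retained_features: list[FeatureRecord]
    isotope_clusters: list[IsotopeCluster]
    adduct_groups: list[AdductGroup]
    isf_assignments: list[ISFAssignment]
    spectrum_sets: list[PrecursorSpectrumSet]
    compounds: list[CompoundTransitions]
    method: MRMMethod
    counts: StageCounts

    @property
    def transitions(self) -> list[TransitionRow]:
        return self.method.transitions


def run_pipeline(
    features: list[FeatureRecord],
    spectra: list[SpectrumRecord],
    config: Optional[RunConfig] = None,
    reference: Optional[list[TransitionRow]] = None,
) -> PipelineResult:
    """Run the full transition-generation workflow on one experimental set."""
    config = config or RunConfig()
    ms2 = [s for s in spectra if s.ms_level >= 2]
    counts = StageCounts(features_total=len(features))

    # DDA coverage on the raw feature set (reported, not a gate)
    raw_sets = fragment_profiles.build_spectrum_sets(features, ms2, config.tracking)
    counts.features_with_ms2 = len(raw_sets)

    deiso, clusters = feature_curation.deisotope(features, config.curation)
    counts.after_isotope_consolidation = len(deiso)
    curated, adduct_groups = feature_curation.group_adducts(deiso, config.curation)
    counts.after_adduct_grouping = len(curated)

    sets_by_id = {s.precursor.feature_id: s for s in raw_sets}
    curated_sets = [
        sets_by_id[f.feature_id] for f in curated if f.feature_id in sets_by_id
    ]
    retained, assignments = isf_filter.filter_isf(curated, curated_sets, config.isf)
    counts.after_isf_removal = len(retained)

    compounds: list[CompoundTransitions] = []
    retained_sets = [
        sets_by_id[f.feature_id] for f in retained if f.feature_id in sets_by_id
    ]
    for sset in retained_sets:
        profiles = fragment_profiles.track_fragments(sset, config.tracking)
        predictions = [predict_ce(p, config.spline) for p in profiles]
        comp = transition_builder.select_transitions(
            sset.precursor, predictions, config.selection, config.scheduling
        )
        if comp is None:
            continue
        if reference:
            comp = transition_builder.apply_reference_guide(
                comp, reference, config.selection
            )
        compounds.append(comp)

    method = transition_builder.merge_experiment_sets(
        [compounds], config.selection, config.scheduling
    )
    counts.compounds_emitted = len(method.compounds)
    log.info(
        "pipeline: %d features -> %d with MS/MS -> %d after isotopes -> "
        "%d after adducts -> %d after ISF removal -> %d compounds",
        counts.features_total,
        counts.features_with_ms2,
        counts.after_isotope_consolidation,
        counts.after_adduct_grouping,
        counts.after_isf_removal,
        counts.compounds_emitted,
    )
    return PipelineResult(
        curated_features=curated,
        retained_features=retained,
        isotope_clusters=clusters,
        adduct_groups=adduct_groups,
        isf_assignments=assignments,
        spectrum_sets=retained_sets,
        compounds=compounds,
        method=method,
        counts=counts,
    )


def detect_features_from_ms1(
    spectra: list[SpectrumRecord],
    ppm: float = 10.0,
    rt_tol_min: float = 0.2,
    min_intensity: float = 0.0,
) -> list[FeatureRecord]:
    """Basic centroid feature extraction from MS1 survey scans.

    Greedy apex picking: peaks across scans are pooled, taken in
    descending intensity, and each seed absorbs all peaks within the ppm
    tolerance and RT window.  The apex peak defines the feature's m/z, RT
    and intensity.  Intended for synthetic or well-behaved centroid data,
    not as a replacement for a full chromatographic peak picker.
    """
    pool: list[tuple[float, float, float, str]] = []  # (intensity, mz, rt, polarity)
    for sp in spectra:
        if sp.ms_level != 1:
            continue
        for mz, inten in sp.peaks:
            if inten >= min_intensity:
                pool.append((inten, mz, sp.rt_min, sp.polarity))
    pool.sort(key=lambda p: (-p[0], p[1]))
    used = [False] * len(pool)
    features: list[FeatureRecord] = []
    for i, (inten, mz, rt, pol) in enumerate(pool):
        if used[i]:
            continue
        tol = ppm * 1e-6 * mz
        for j in range(i, len(pool)):
            if used[j]:
                continue
            _, mz_j, rt_j, pol_j = pool[j]
            if pol_j == pol and abs(mz_j - mz) <= tol and abs(rt_j - rt) <= rt_tol_min:
                used[j] = True
        features.append(
            FeatureRecord(
                feature_id=f"D{len(features):05d}",
                mz=mz,
                rt_min=rt,
                intensity=inten,
                polarity=pol,
            )
        )
    features.sort(key=lambda f: (f.rt_min, f.mz))
    return features
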