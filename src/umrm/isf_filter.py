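"""Empirical in-source fragment (ISF) filtering of MS1 features.

An in-source fragment is a fragment ion formed in the ion source before
mass selection; it shows up as a spurious MS1 "precursor" feature that
coelutes with its intact parent.  Left in place, such features propagate
into transition lists as nonspecific quantitative targets.

A feature F is classified as ISF-derived only when three independent
criteria converge on some candidate parent P:

1. accurate-mass association — P's MS/MS contains a fragment matching
   F's m/z within the ppm tolerance;
2. chromatographic coelution — |RT(F) − RT(P)| ≤ the coelution window
   (default ±0.05 min);
3. collision-energy dependence — that fragment is already detected in
   P's 0 eV spectrum and persists (or grows) at higher energies, the
   signature of source fragmentation rather than an intact molecular ion.

0 eV spectra are a low-energy reference, not assumed fragment-free.
Every removal is justified by a recorded assignment naming the parent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .config import ISFConfig
from .fragment_profiles import PrecursorSpectrumSet
from .records import FeatureRecord, SpectrumRecord

log = logging.getLogger(__name__)

DETECTED_PERSISTS = "detected_at_0eV_and_persists"
NOT_SUPPORTED = "not_supported"


@dataclass
class ISFAssignment:
    """Evidence trail for one fragment-feature/parent-feature pair."""

    fragment_feature: FeatureRecord
    parent_feature: FeatureRecord
    delta_rt_min: float
    mass_match_ppm: float
    ce_behavior: str
    verdict: str  # "isf_derived" or "retained"


def _peak_intensity(spectrum: SpectrumRecord, mz: float, ppm: float, noise: float) -> float:
    """Max intensity of peaks matching ``mz`` within ppm, above noise; 0 if none."""
    tol = ppm * 1e-6 * mz
    best = 0.0
    for pmz, inten in spectrum.peaks:
        if abs(pmz - mz) <= tol and inten > noise:
            best = max(best, inten)
    return best


def _ce_behavior(
    spectra: dict[float, SpectrumRecord], frag_mz: float, cfg: ISFConfig
) -> tuple[str, float]:
    """Evaluate criterion 3 against one parent's spectrum set.

    Returns the behavior label and the ppm error of the best 0 eV match.
    """
    zero = spectra.get(0.0)
    if zero is None:
        return NOT_SUPPORTED, float("inf")
    i0 = _peak_intensity(zero, frag_mz, cfg.ppm, cfg.ms2_noise)
    if i0 <= 0:
        return NOT_SUPPORTED, float("inf")
    hi = max(
        (
            _peak_intensity(sp, frag_mz, cfg.ppm, cfg.ms2_noise)
            for ce, sp in spectra.items()
            if ce > 0
        ),
        default=0.0,
    )
    if hi >= cfg.persistence_factor * i0:
        tol = cfg.ppm * 1e-6 * frag_mz
        best_ppm = min(
            (
                abs(pmz - frag_mz) / frag_mz * 1e6
                for pmz, inten in zero.peaks
                if abs(pmz - frag_mz) <= tol and inten > cfg.ms2_noise
            ),
            default=float("inf"),
        )
        return DETECTED_PERSISTS, best_ppm
    return NOT_SUPPORTED, float("inf")


def filter_isf(
    features: list[FeatureRecord],
    spectrum_sets: list[PrecursorSpectrumSet],
    cfg: ISFConfig | None = None,
) -> tuple[list[FeatureRecord], list[ISFAssignment]]:
    """Partition features into retained precursors and ISF-derived features.

    ``spectrum_sets`` supplies each candidate parent's MS/MS spectra per
    collision energy (a feature without MS/MS cannot act as a parent but
    can still be flagged as the in-source fragment of another).  Parent
    candidates must exceed the fragment feature's m/z by at least
    ``parent_min_mass_gap_da`` and carry at least
    ``parent_min_intensity_ratio`` of its intensity.  When several parents
    qualify, the assignment records the one with the smallest ppm error
    (ties broken by smaller |ΔRT|); the verdict is the same either way.
    """
    cfg = cfg or ISFConfig()
    sets_by_id = {s.precursor.feature_id: s for s in spectrum_sets}
    retained: list[FeatureRecord] = []
    assignments: list[ISFAssignment] = []
    for feat in features:
        matches: list[ISFAssignment] = []
        for parent in features:
            if parent.feature_id == feat.feature_id:
                continue
            if parent.mz <= feat.mz + cfg.parent_min_mass_gap_da:
                continue
            if parent.intensity < cfg.parent_min_intensity_ratio * feat.intensity:
                continue
            d_rt = feat.rt_min - parent.rt_min
            if abs(d_rt) > cfg.rt_window_min:
                continue
            pset = sets_by_id.get(parent.feature_id)
            if pset is None:
                continue
            behavior, ppm_err = _ce_behavior(pset.spectra, feat.mz, cfg)
            if behavior == NOT_SUPPORTED:
                continue
            matches.append(
                ISFAssignment(
                    fragment_feature=feat,
                    parent_feature=parent,
                    delta_rt_min=d_rt,
                    mass_match_ppm=ppm_err,
                    ce_behavior=behavior,
                    verdict="isf_derived",
                )
            )
        if matches:
            best = min(matches, key=lambda a: (a.mass_match_ppm, abs(a.delta_rt_min)))
            assignments.append(best)
        else:
            retained.append(feat)
    log.info(
        "ISF filter: %d/%d features classified as in-source fragments",
        len(assignments),
        len(features),
    )
    return retained, assignments
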