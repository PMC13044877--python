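"""Precursor–spectrum association and cross-energy fragment tracking.

Each curated precursor is matched to at most one MS/MS spectrum per
sampled collision energy (0/10/20/40 eV).  Within a precursor's spectrum
set, the top ten fragment peaks per energy are tracked across energies by
iterative matching against intensity-weighted group centroids with a
±0.5 Da tolerance, yielding one collision-energy–intensity profile per
recurring fragment ion.  Profiles observed at three or more energies are
eligible for spline fitting; profiles with discontinuous intensity
behavior across energies are flagged irregular and excluded from
quantifier candidacy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .config import TrackingConfig
from .records import FeatureRecord, SpectrumRecord

log = logging.getLogger(__name__)


@dataclass
class PrecursorSpectrumSet:
    """One precursor with its MS/MS spectrum per sampled collision energy."""

    precursor: FeatureRecord
    spectra: dict[float, SpectrumRecord]


@dataclass
class FragmentGroup:
    """A recurring fragment ion tracked across collision energies.

    ``group_mz`` is the intensity-weighted centroid of the member peaks;
    ``observations`` maps collision energy (eV) to observed intensity.
    A missing energy means the fragment was not observed there, not that
    its intensity was zero.
    """

    group_mz: float
    observations: dict[float, float]
    _weight: float = 0.0

    @property
    def n_energies(self) -> int:
        return len(self.observations)

    def add(self, ce: float, mz: float, intensity: float) -> None:
        total = self._weight + intensity
        self.group_mz = (self.group_mz * self._weight + mz * intensity) / total
        self._weight = total
        self.observations[ce] = intensity


@dataclass
class CEProfile:
    """Per precursor–fragment collision-energy response profile."""

    precursor_mz: float
    precursor_rt_min: float
    polarity: str
    fragment: FragmentGroup
    irregular: bool = False

    @property
    def eligible_for_spline(self) -> bool:
        return self.fragment.n_energies >= 3


def build_spectrum_sets(
    precursors: list[FeatureRecord],
    ms2: list[SpectrumRecord],
    cfg: TrackingConfig | None = None,
) -> list[PrecursorSpectrumSet]:
    """Map each precursor to its best MS/MS spectrum per collision energy.

    A spectrum matches a precursor when its isolated m/z lies within the
    ppm tolerance and its RT within the association window, with matching
    polarity.  Duplicate spectra at one energy resolve to the highest TIC.
    Precursors with no MS/MS anywhere are dropped; the DDA coverage count
    is logged.
    """
    cfg = cfg or TrackingConfig()
    sets: list[PrecursorSpectrumSet] = []
    n_covered = 0
    for prec in precursors:
        chosen: dict[float, SpectrumRecord] = {}
        for sp in ms2:
            if sp.ms_level < 2 or sp.precursor_mz is None or sp.collision_energy_ev is None:
                continue
            if sp.polarity != prec.polarity:
                continue
            if abs(sp.precursor_mz - prec.mz) / prec.mz * 1e6 > cfg.precursor_ppm:
                continue
            if abs(sp.rt_min - prec.rt_min) > cfg.precursor_rt_min:
                continue
            ce = float(sp.collision_energy_ev)
            if ce not in chosen or sp.tic > chosen[ce].tic:
                chosen[ce] = sp
        if chosen:
            n_covered += 1
            sets.append(PrecursorSpectrumSet(precursor=prec, spectra=chosen))
    log.info(
        "DDA coverage: %d/%d precursors have MS/MS (%.1f%%)",
        n_covered,
        len(precursors),
        100.0 * n_covered / len(precursors) if precursors else 0.0,
    )
    return sets


def track_fragments(
    spectrum_set: PrecursorSpectrumSet, cfg: TrackingConfig | None = None
) -> list[CEProfile]:
    """Track fragment ions across collision energies for one precursor.

    Per energy, the top ``top_n_fragments`` peaks (default 10) enter the
    pool after excluding anything within 2.0 Da of the precursor m/z
    (unfragmented-precursor survival must never become a transition).
    Candidates are then grouped in descending intensity order: a peak
    joins the nearest group centroid within ±0.5 Da that does not already
    hold an observation at its energy, otherwise it seeds a new group.
    Centroids are intensity-weighted and updated as members join, which
    keeps grouping deterministic and prevents chaining drift.
    """
    cfg = cfg or TrackingConfig()
    prec = spectrum_set.precursor
    candidates: list[tuple[float, float, float]] = []  # (intensity, mz, ce)
    for ce, sp in spectrum_set.spectra.items():
        peaks = [
            (mz, inten)
            for mz, inten in sp.peaks
            # 1 nDa slack keeps the boundary decision free of float round-off
            if abs(mz - prec.mz) >= cfg.precursor_exclusion_da - 1e-9 and inten > 0
        ]
        peaks.sort(key=lambda p: (-p[1], p[0]))
        for mz, inten in peaks[: cfg.top_n_fragments]:
            candidates.append((inten, mz, ce))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    groups: list[FragmentGroup] = []
    for inten, mz, ce in candidates:
        open_groups = [
            g
            for g in groups
            if abs(g.group_mz - mz) <= cfg.group_tol_da and ce not in g.observations
        ]
        if open_groups:
            best = min(open_groups, key=lambda g: abs(g.group_mz - mz))
            best.add(ce, mz, inten)
        else:
            groups.append(FragmentGroup(group_mz=mz, observations={ce: inten}, _weight=inten))

    profiles = [
        CEProfile(
            precursor_mz=prec.mz,
            precursor_rt_min=prec.rt_min,
            polarity=prec.polarity,
            fragment=g,
        )
        for g in groups
    ]
    return [flag_irregular(p, cfg) for p in profiles]


def flag_irregular(profile: CEProfile, cfg: TrackingConfig | None = None) -> CEProfile:
    """Flag profiles whose intensity collapses and then rebounds across CE.

    Ordered by collision energy, a profile is irregular when it falls
    below ``trough_fraction`` of its maximum and later rebounds above
    ``rebound_fraction`` of the maximum — discontinuous behavior that
    makes a fragment unreliable as a quantifier.  Applied only to
    profiles observed at three or more energies; sparser profiles are
    handled by the observed-CE fallback instead.
    """
    cfg = cfg or TrackingConfig()
    obs = profile.fragment.observations
    if len(obs) < cfg.min_energies_for_spline:
        profile.irregular = False
        return profile
    intens = [obs[ce] for ce in sorted(obs)]
    peak = max(intens)
    running_max = 0.0
    in_trough = False
    irregular = False
    for v in intens:
        if v < cfg.trough_fraction * peak:
            # a trough only counts after the profile has been above that level
            if running_max >= cfg.trough_fraction * peak:
                in_trough = True
        elif in_trough and v > cfg.rebound_fraction * peak:
            irregular = True
            break
        running_max = max(running_max, v)
    profile.irregular = irregular
    return profile
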