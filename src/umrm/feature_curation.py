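"""Isotope consolidation and adduct grouping of MS1 features.

Deisotoping merges isotopologue series (spaced ~1.003355/z Da, coeluting)
into their monoisotopic member.  Adduct grouping then links coeluting
features whose m/z differences match known charge-carrier offsets
(H+, Na+, NH4+, K+ in positive mode; -H, +HCOO in negative mode) and
keeps one representative precursor per group.  Adduct species are treated
as analytically valid precursors, not as noise: grouping only removes
*redundant* adduct forms of the same neutral molecule, never collapses
everything onto [M+H]+.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import ISOTOPE_SPACING_DA, CurationConfig
from .records import FeatureRecord

log = logging.getLogger(__name__)


@dataclass
class IsotopeCluster:
    """A consolidated isotopologue series; ``monoisotopic`` survives."""

    members: list[FeatureRecord]
    monoisotopic: FeatureRecord
    charge: int


@dataclass
class AdductGroup:
    """Coeluting adduct forms of one neutral molecule."""

    members: list[tuple[FeatureRecord, str]]
    representative: FeatureRecord
    neutral_mass: float


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


def _coelute(a: FeatureRecord, b: FeatureRecord, window: float) -> bool:
    return abs(a.rt_min - b.rt_min) <= window


def _seed_order(features: list[FeatureRecord]) -> list[FeatureRecord]:
    # greedy seeding by descending intensity; ties broken by ascending m/z
    return sorted(features, key=lambda f: (-f.intensity, f.mz))


def deisotope(
    features: list[FeatureRecord], cfg: CurationConfig | None = None
) -> tuple[list[FeatureRecord], list[IsotopeCluster]]:
    """Consolidate isotopologue series into monoisotopic features.

    Clusters are seeded greedily in descending intensity order.  For each
    seed and each charge state, consecutive isotopologues are collected
    upward in m/z (spacing 1.003355/z within the ppm tolerance, coeluting
    within the RT window); the charge yielding the most members wins, ties
    going to the lower charge.  A feature joins at most one cluster.
    Returned features are the monoisotopic representatives plus everything
    left unclustered, in the original input order.
    """
    cfg = cfg or CurationConfig()
    if not features:
        return [], []
    assigned: set[str] = set()
    clusters: list[IsotopeCluster] = []
    by_id = {f.feature_id: f for f in features}
    for seed in _seed_order(features):
        if seed.feature_id in assigned:
            continue
        best_members: list[FeatureRecord] = [seed]
        best_charge = 0
        for charge in cfg.charges:
            spacing = ISOTOPE_SPACING_DA / charge
            members = [seed]
            current_mz = seed.mz
            for _ in range(cfg.max_isotope_shift):
                target = current_mz + spacing
                cands = [
                    f
                    for f in features
                    if f.feature_id not in assigned
                    and f.feature_id != seed.feature_id
                    and f not in members
                    and _ppm(f.mz, target) <= cfg.mz_tol_ppm
                    and _coelute(f, seed, cfg.rt_window_min)
                ]
                if not cands:
                    break
                nxt = min(cands, key=lambda f: _ppm(f.mz, target))
                members.append(nxt)
                current_mz = nxt.mz
            if len(members) > len(best_members):
                best_members = members
                best_charge = charge
        if len(best_members) >= 2:
            # monotone-decreasing envelope expected for small molecules; log only
            intens = [m.intensity for m in best_members]
            if any(b > a for a, b in zip(intens, intens[1:])):
                log.debug(
                    "isotope cluster seeded at %s has a non-decreasing envelope %s",
                    seed.feature_id,
                    intens,
                )
            clusters.append(
                IsotopeCluster(
                    members=best_members, monoisotopic=best_members[0], charge=best_charge
                )
            )
            assigned.update(m.feature_id for m in best_members)
    survivors_ids = set(by_id) - assigned | {c.monoisotopic.feature_id for c in clusters}
    survivors = [f for f in features if f.feature_id in survivors_ids]
    return survivors, clusters


def group_adducts(
    features: list[FeatureRecord], cfg: CurationConfig | None = None
) -> tuple[list[FeatureRecord], list[AdductGroup]]:
    """Group coeluting redundant adduct forms; keep one representative each.

    Two coeluting features are linked when their m/z difference matches
    the difference of two adduct offsets of the same polarity within the
    ppm tolerance (evaluated on the higher m/z).  Groups are the connected
    components of that relation; the most intense member is retained as
    the representative precursor.  Features matching no adduct relation
    pass through untouched as independent precursors.
    """
    cfg = cfg or CurationConfig()
    if not features:
        return [], []
    # pairwise label differences per polarity
    diffs: dict[str, list[tuple[float, str, str]]] = {}
    for la, (da, pa) in cfg.adduct_deltas.items():
        for lb, (db, pb) in cfg.adduct_deltas.items():
            if pa != pb or db <= da:
                continue
            diffs.setdefault(pa, []).append((db - da, la, lb))

    parent = {f.feature_id: f.feature_id for f in features}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    labels: dict[str, str] = {}
    ordered = sorted(features, key=lambda f: f.mz)
    for i, lo in enumerate(ordered):
        for hi in ordered[i + 1 :]:
            if hi.mz - lo.mz > 60.0:  # largest configured delta difference
                break
            if lo.polarity != hi.polarity or not _coelute(lo, hi, cfg.rt_window_min):
                continue
            delta = hi.mz - lo.mz
            for d, la, lb in diffs.get(lo.polarity, []):
                if abs(delta - d) <= cfg.mz_tol_ppm * 1e-6 * hi.mz:
                    union(lo.feature_id, hi.feature_id)
                    labels.setdefault(lo.feature_id, la)
                    labels.setdefault(hi.feature_id, lb)
                    break

    comps: dict[str, list[FeatureRecord]] = {}
    for f in features:
        comps.setdefault(find(f.feature_id), []).append(f)

    groups: list[AdductGroup] = []
    dropped: set[str] = set()
    for members in comps.values():
        if len(members) < 2:
            continue
        rep = max(members, key=lambda f: f.intensity)
        rep_label = labels.get(rep.feature_id, "")
        delta = cfg.adduct_deltas.get(rep_label, (0.0, rep.polarity))[0]
        groups.append(
            AdductGroup(
                members=[(m, labels.get(m.feature_id, "?")) for m in members],
                representative=rep,
                neutral_mass=rep.mz - delta,
            )
        )
        dropped.update(m.feature_id for m in members if m.feature_id != rep.feature_id)
    survivors = [f for f in features if f.feature_id not in dropped]
    return survivors, groups


def curate(
    features: list[FeatureRecord], cfg: CurationConfig | None = None
) -> tuple[list[FeatureRecord], list[IsotopeCluster], list[AdductGroup]]:
    """Deisotope then adduct-group; convenience wrapper used by the pipeline."""
    cfg = cfg or CurationConfig()
    deiso, clusters = deisotope(features, cfg)
    curated, groups = group_adducts(deiso, cfg)
    return curated, clusters, groups
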