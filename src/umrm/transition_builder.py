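"""Quantifier/qualifier selection, reference guidance, and method merging.

The quantifier is the most intense *stable* fragment — stable meaning a
profile observed at three or more collision energies without irregular
intensity behavior.  Qualifiers are the next most intense fragments
meeting the same reproducibility criteria; every emitted transition keeps
a ≥2.0 Da mass separation from its precursor.  Compounds whose spectra
yield a single reproducible fragment emit a quantifier-only transition.
Transitions built per experimental set are merged into one scheduled
dynamic-MRM method (±0.3 min windows, 500 ms cycle time) with duplicate
compounds collapsed across sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .ce_optimizer import CEPrediction
from .config import SchedulingConfig, SelectionConfig
from .records import (
    NEGATIVE,
    POSITIVE,
    QUALIFIER,
    QUANTIFIER,
    FeatureRecord,
    TransitionRow,
)

log = logging.getLogger(__name__)

EMPIRICAL = "empirical"
REFERENCE_GUIDED = "reference_guided"


@dataclass
class CompoundTransitions:
    """Selected transitions for one precursor."""

    precursor: FeatureRecord
    quantifier: CEPrediction
    qualifiers: list[CEPrediction]
    rt_min: float
    rt_window_min: float
    mode: str = EMPIRICAL
    single_transition: bool = False  # true when only a fallback profile existed

    @property
    def label(self) -> str:
        return f"{self.precursor.mz:.4f}@{self.rt_min:.2f}"

    @property
    def expected_transition_ratios(self) -> list[float]:
        """Expected qualifier/quantifier intensity ratios.

        Exported as metadata to support transition-ratio consistency
        checks on acquired data; ratio QC is reporting, never a gate.
        """
        q = self.quantifier.predicted_max_intensity
        if q <= 0:
            return [float("nan")] * len(self.qualifiers)
        return [p.predicted_max_intensity / q for p in self.qualifiers]


@dataclass
class MRMMethod:
    """A scheduled dynamic-MRM method: the union of compound transitions."""

    compounds: list[CompoundTransitions]
    cycle_time_ms: float
    polarity_switching: bool

    @property
    def transitions(self) -> list[TransitionRow]:
        rows: list[TransitionRow] = []
        for c in self.compounds:
            rows.append(_to_row(c, c.quantifier, QUANTIFIER))
            rows.extend(_to_row(c, q, QUALIFIER) for q in c.qualifiers)
        return rows


def _to_row(compound: CompoundTransitions, pred: CEPrediction, role: str) -> TransitionRow:
    return TransitionRow(
        compound_label=compound.label,
        precursor_mz=compound.precursor.mz,
        fragment_mz=pred.profile.fragment.group_mz,
        polarity=compound.precursor.polarity,
        collision_energy_ev=pred.ce_opt_ev,
        rt_min=compound.rt_min,
        rt_window_min=compound.rt_window_min,
        role=role,
    )


def _separated(pred: CEPrediction, precursor_mz: float, min_sep: float) -> bool:
    # 1 nDa slack keeps the boundary decision free of float round-off
    return abs(precursor_mz - pred.profile.fragment.group_mz) >= min_sep - 1e-9


def _rank_key(pred: CEPrediction) -> tuple:
    # most intense first; ties -> more energies, then lower fragment m/z
    return (
        -pred.predicted_max_intensity,
        -pred.profile.fragment.n_energies,
        pred.profile.fragment.group_mz,
    )


def select_transitions(
    precursor: FeatureRecord,
    predictions: list[CEPrediction],
    cfg: SelectionConfig | None = None,
    scheduling: SchedulingConfig | None = None,
) -> Optional[CompoundTransitions]:
    """Pick the quantifier and qualifier transitions for one precursor.

    Eligible candidates are spline-fitted (≥3 energies), non-irregular,
    and ≥2.0 Da from the precursor.  The quantifier is the highest
    predicted-intensity eligible candidate; qualifiers are the next
    ``n_qualifiers`` in rank.  When no eligible candidate exists,
    fallback (sparse-coverage) predictions supply a single quantifier
    transition; with no usable candidate at all the compound is dropped
    with a diagnostic.
    """
    cfg = cfg or SelectionConfig()
    scheduling = scheduling or SchedulingConfig()
    usable = [p for p in predictions if _separated(p, precursor.mz, cfg.min_separation_da)]
    eligible = [
        p
        for p in usable
        if p.fitted and p.profile.eligible_for_spline and not p.profile.irregular
    ]
    eligible.sort(key=_rank_key)
    if eligible:
        quantifier = eligible[0]
        qualifiers = eligible[1 : 1 + cfg.n_qualifiers]
        single = False
    else:
        fallbacks = sorted((p for p in usable if not p.fitted), key=_rank_key)
        if not fallbacks:
            log.warning(
                "precursor m/z %.4f @ %.2f min: no stable fragment profile; compound dropped",
                precursor.mz,
                precursor.rt_min,
            )
            return None
        quantifier = fallbacks[0]
        qualifiers = []
        single = True
    return CompoundTransitions(
        precursor=precursor,
        quantifier=quantifier,
        qualifiers=qualifiers,
        rt_min=precursor.rt_min,
        rt_window_min=scheduling.rt_window_min,
        mode=EMPIRICAL,
        single_transition=single,
    )


def apply_reference_guide(
    compound: CompoundTransitions,
    reference: list[TransitionRow],
    cfg: SelectionConfig | None = None,
) -> CompoundTransitions:
    """Promote a validated reference fragment to quantifier, keeping the empirical CE.

    Reference rows are matched to the compound's precursor by m/z (ppm)
    and polarity; a reference quantifier fragment matching an observed
    fragment group within ±0.5 Da is promoted to the quantifier slot with
    its collision energy taken from the empirical model, never from the
    reference.  Unmatched reference fragments are ignored and the
    compound stays fully empirical.
    """
    cfg = cfg or SelectionConfig()
    prec = compound.precursor
    ref_rows = [
        r
        for r in reference
        if r.polarity == prec.polarity
        and abs(r.precursor_mz - prec.mz) / prec.mz * 1e6 <= cfg.dedup_ppm
    ]
    ref_quants = [r for r in ref_rows if r.role == QUANTIFIER] or ref_rows
    if not ref_quants:
        return compound
    candidates = [compound.quantifier] + compound.qualifiers
    for ref in ref_quants:
        matched = [
            p
            for p in candidates
            if abs(p.profile.fragment.group_mz - ref.fragment_mz) <= cfg.dedup_fragment_da
        ]
        if not matched:
            continue
        promoted = min(
            matched, key=lambda p: abs(p.profile.fragment.group_mz - ref.fragment_mz)
        )
        others = [p for p in candidates if p is not promoted]
        compound.quantifier = promoted
        compound.qualifiers = others[: cfg.n_qualifiers]
        compound.mode = REFERENCE_GUIDED
        return compound
    return compound


def merge_experiment_sets(
    sets: list[list[CompoundTransitions]],
    cfg: SelectionConfig | None = None,
    scheduling: SchedulingConfig | None = None,
) -> MRMMethod:
    """Union compound transitions across experimental sets into one method.

    Duplicates — same polarity, precursor m/z within ppm, quantifier
    fragment within ±0.5 Da, RT within the scheduling window — collapse
    to the instance whose quantifier has the higher predicted intensity.
    Polarity switching is enabled when both polarities are present.
    """
    cfg = cfg or SelectionConfig()
    scheduling = scheduling or SchedulingConfig()
    merged: list[CompoundTransitions] = []
    for cset in sets:
        for comp in cset:
            dup = None
            for kept in merged:
                if kept.precursor.polarity != comp.precursor.polarity:
                    continue
                if (
                    abs(kept.precursor.mz - comp.precursor.mz)
                    / comp.precursor.mz
                    * 1e6
                    > cfg.dedup_ppm
                ):
                    continue
                if (
                    abs(
                        kept.quantifier.profile.fragment.group_mz
                        - comp.quantifier.profile.fragment.group_mz
                    )
                    > cfg.dedup_fragment_da
                ):
                    continue
                if abs(kept.rt_min - comp.rt_min) > scheduling.rt_window_min:
                    continue
                dup = kept
                break
            if dup is None:
                merged.append(comp)
            elif (
                comp.quantifier.predicted_max_intensity
                > dup.quantifier.predicted_max_intensity
            ):
                merged[merged.index(dup)] = comp
    merged.sort(key=lambda c: (c.rt_min, c.precursor.mz))
    polarities = {c.precursor.polarity for c in merged}
    return MRMMethod(
        compounds=merged,
        cycle_time_ms=scheduling.cycle_time_ms,
        polarity_switching=polarities == {POSITIVE, NEGATIVE},
    )
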