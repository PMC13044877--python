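"""Benchmarking of transition tables against a reference.

Compares an emitted transition table with an independently optimized one
using three metrics: fragment m/z agreement within ±0.5 Da, collision
energy prediction error ΔCE (emitted − reference) for matched quantifier
fragments, and quantifier/qualifier overlap.  The ΔCE summary mirrors the
standard cross-platform reporting convention: median ΔCE (directional
bias), median |ΔCE| (typical magnitude), and the fractions within ±5 and
±10 eV.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import QUALIFIER, QUANTIFIER, TransitionRow

FRAGMENT_TOL_DA = 0.5


def delta_ce_summary(deltas: list[float]) -> dict:
    """Summary statistics of a ΔCE distribution (eV)."""
    if not deltas:
        return {
            "n": 0,
            "median_dce_ev": float("nan"),
            "median_abs_dce_ev": float("nan"),
            "pct_within_5ev": float("nan"),
            "pct_within_10ev": float("nan"),
        }
    arr = np.asarray(deltas, dtype=float)
    return {
        "n": int(arr.size),
        "median_dce_ev": float(np.median(arr)),
        "median_abs_dce_ev": float(np.median(np.abs(arr))),
        "pct_within_5ev": float(100.0 * np.mean(np.abs(arr) <= 5.0)),
        "pct_within_10ev": float(100.0 * np.mean(np.abs(arr) <= 10.0)),
    }


@dataclass
class BenchmarkReport:
    n_predicted_compounds: int
    n_reference_compounds: int
    n_matched_compounds: int
    fragment_match_rate: float
    quantifier_overlap: float
    qualifier_overlap: float
    ce_summary: dict
    per_compound: list[dict] = field(default_factory=list)
    strata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_predicted_compounds": self.n_predicted_compounds,
            "n_reference_compounds": self.n_reference_compounds,
            "n_matched_compounds": self.n_matched_compounds,
            "fragment_match_rate": self.fragment_match_rate,
            "quantifier_overlap": self.quantifier_overlap,
            "qualifier_overlap": self.qualifier_overlap,
            "ce_summary": self.ce_summary,
            "strata": self.strata,
        }


def _by_compound(rows: list[TransitionRow]) -> dict[str, list[TransitionRow]]:
    out: dict[str, list[TransitionRow]] = {}
    for r in rows:
        out.setdefault(r.compound_label, []).append(r)
    return out


def _quantifier(rows: list[TransitionRow]) -> Optional[TransitionRow]:
    for r in rows:
        if r.role == QUANTIFIER:
            return r
    return None


def benchmark_transitions(
    predicted: list[TransitionRow],
    reference: list[TransitionRow],
    ppm: float = 10.0,
    fragment_tol_da: float = FRAGMENT_TOL_DA,
    groups: Optional[dict[str, str]] = None,
) -> BenchmarkReport:
    """Benchmark a predicted transition table against a reference table.

    Compounds are matched by precursor m/z (ppm) and polarity, nearest
    m/z first.  For each matched compound the quantifier fragments are
    compared within ±0.5 Da; ΔCE is evaluated on matched quantifier
    fragments.  ``groups`` optionally maps reference compound labels to a
    stratum name; the ΔCE summary is then also reported per stratum.
    """
    pred = _by_compound(predicted)
    ref = _by_compound(reference)
    pred_list = [(label, rows) for label, rows in pred.items()]
    used: set[str] = set()
    per_compound: list[dict] = []
    deltas: list[float] = []
    strat_deltas: dict[str, list[float]] = {}
    n_frag_pairs = 0
    n_frag_matched = 0
    n_quant_overlap = 0
    n_qual_pairs = 0
    n_qual_matched = 0

    for ref_label, ref_rows in ref.items():
        rq = _quantifier(ref_rows)
        anchor = rq or ref_rows[0]
        best = None
        best_err = float("inf")
        for label, rows in pred_list:
            if label in used:
                continue
            pq = _quantifier(rows) or rows[0]
            if pq.polarity != anchor.polarity:
                continue
            err = abs(pq.precursor_mz - anchor.precursor_mz) / anchor.precursor_mz * 1e6
            if err <= ppm and err < best_err:
                best, best_err = (label, rows), err
        if best is None:
            continue
        used.add(best[0])
        pq = _quantifier(best[1]) or best[1][0]

        # fragment agreement over all reference transitions
        pred_frags = [r.fragment_mz for r in best[1]]
        for rr in ref_rows:
            n_frag_pairs += 1
            if any(abs(f - rr.fragment_mz) <= fragment_tol_da for f in pred_frags):
                n_frag_matched += 1

        quant_matched = rq is not None and abs(pq.fragment_mz - rq.fragment_mz) <= fragment_tol_da
        if quant_matched:
            n_quant_overlap += 1
            d = pq.collision_energy_ev - rq.collision_energy_ev
            deltas.append(d)
            if groups and ref_label in groups:
                strat_deltas.setdefault(groups[ref_label], []).append(d)
        ref_quals = [r for r in ref_rows if r.role == QUALIFIER]
        pred_quals = [r.fragment_mz for r in best[1] if r.role == QUALIFIER]
        for rr in ref_quals:
            n_qual_pairs += 1
            if any(abs(f - rr.fragment_mz) <= fragment_tol_da for f in pred_quals):
                n_qual_matched += 1
        per_compound.append(
            {
                "reference": ref_label,
                "predicted": best[0],
                "precursor_ppm_error": best_err,
                "quantifier_matched": quant_matched,
                "delta_ce_ev": (
                    pq.collision_energy_ev - rq.collision_energy_ev
                    if quant_matched
                    else None
                ),
            }
        )

    n_matched = len(per_compound)
    report = BenchmarkReport(
        n_predicted_compounds=len(pred),
        n_reference_compounds=len(ref),
        n_matched_compounds=n_matched,
        fragment_match_rate=(n_frag_matched / n_frag_pairs) if n_frag_pairs else 0.0,
        quantifier_overlap=(n_quant_overlap / n_matched) if n_matched else 0.0,
        qualifier_overlap=(n_qual_matched / n_qual_pairs) if n_qual_pairs else 0.0,
        ce_summary=delta_ce_summary(deltas),
        per_compound=per_compound,
        strata={k: delta_ce_summary(v) for k, v in sorted(strat_deltas.items())},
    )
    return report
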