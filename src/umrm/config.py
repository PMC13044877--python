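"""Configuration dataclasses for every pipeline stage.

Defaults encode the workflow's operating parameters: 10 ppm mass
tolerance, a ±0.05 min coelution window, the 5–40 eV collision-energy
range sampled at 0/10/20/40 eV, ±0.5 Da cross-energy fragment grouping,
a ≥2.0 Da precursor–fragment separation, and ±0.3 min scheduling windows
with a 500 ms cycle time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

#: Mass difference between successive isotopologues (Da), 13C - 12C.
ISOTOPE_SPACING_DA = 1.003355

PROTON_MASS = 1.007276

#: Adduct label -> (mass added to the neutral molecule, polarity).
#: Singly charged species only; m/z = neutral_mass + delta.
DEFAULT_ADDUCT_DELTAS: dict[str, tuple[float, str]] = {
    "[M+H]+": (1.007276, "positive"),
    "[M+Na]+": (22.989218, "positive"),
    "[M+NH4]+": (18.033823, "positive"),
    "[M+K]+": (38.963158, "positive"),
    "[M-H]-": (-1.007276, "negative"),
    "[M+HCOO]-": (44.998201, "negative"),
}


@dataclass
class CurationConfig:
    """Deisotoping and adduct-grouping parameters."""

    mz_tol_ppm: float = 10.0
    rt_window_min: float = 0.05          # coelution half-window
    charges: tuple[int, ...] = (1, 2, 3)
    max_isotope_shift: int = 3           # isotopologues tracked above monoisotopic
    adduct_deltas: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_DELTAS)
    )


@dataclass
class ISFConfig:
    """In-source-fragment filter parameters.

    A feature is removed as ISF-derived only when all three empirical
    criteria hold against some coeluting higher-mass parent: accurate-mass
    match of a parent MS/MS fragment (``ppm``), coelution
    (``rt_window_min``), and detection at 0 eV that persists at higher
    energy (``persistence_factor`` of the 0 eV intensity).
    """

    rt_window_min: float = 0.05
    ppm: float = 10.0
    persistence_factor: float = 0.5
    parent_min_mass_gap_da: float = 2.0
    parent_min_intensity_ratio: float = 0.1  # parent >= ratio * fragment intensity
    ms2_noise: float = 0.0                   # detection threshold for MS2 peaks


@dataclass
class TrackingConfig:
    """Precursor-spectrum association and cross-energy fragment tracking."""

    precursor_ppm: float = 10.0
    precursor_rt_min: float = 0.05
    top_n_fragments: int = 10
    group_tol_da: float = 0.5
    precursor_exclusion_da: float = 2.0
    rebound_fraction: float = 0.5
    trough_fraction: float = 0.1
    min_energies_for_spline: int = 3


@dataclass
class SplineConfig:
    """Collision-energy spline fit and argmax search."""

    spline_degree: int = 2       # quadratic interpolating spline
    grid_step_ev: float = 0.1
    ce_floor_ev: float = 5.0
    ce_ceiling_ev: float = 40.0
    #: Optional user hook applied to the predicted CE before clamping.
    ce_adjust_fn: Optional[Callable[[float], float]] = None


@dataclass
class SelectionConfig:
    """Quantifier/qualifier selection and cross-set merging."""

    n_qualifiers: int = 1
    min_separation_da: float = 2.0
    dedup_ppm: float = 10.0
    dedup_fragment_da: float = 0.5


@dataclass
class SchedulingConfig:
    """Dynamic-MRM scheduling parameters."""

    rt_window_min: float = 0.3   # half-width around pooled-sample RT
    cycle_time_ms: float = 500.0


@dataclass
class RunConfig:
    """Bundle of all stage configs for one pipeline run."""

    curation: CurationConfig = field(default_factory=CurationConfig)
    isf: ISFConfig = field(default_factory=ISFConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    spline: SplineConfig = field(default_factory=SplineConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    scheduling: SchedulingConfig = field(default_factory=SchedulingConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        # callables are not serializable; record presence only
        d["spline"]["ce_adjust_fn"] = (
            None if self.spline.ce_adjust_fn is None else "<user hook>"
        )
        return d
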