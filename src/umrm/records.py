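"""Core domain records shared across the pipeline.

Everything downstream of file I/O works on these lightweight dataclasses:
MS1 features, MS1/MS2 spectra, and the rows of the vendor-agnostic
transition table that is the workflow's final product.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

POSITIVE = "positive"
NEGATIVE = "negative"

#: Sampled collision energies of the stepped-energy DDA acquisition (eV).
SAMPLED_ENERGIES = (0.0, 10.0, 20.0, 40.0)


@dataclass
class SpectrumRecord:
    """One centroided spectrum (MS1 or MS2) read from an mzML run.

    ``peaks`` is a list of ``(mz, intensity)`` tuples sorted ascending in
    m/z.  MS2 records carry the isolated precursor m/z and, when encoded
    in the file, the applied collision energy in eV.
    """

    scan_id: str
    ms_level: int
    rt_min: float
    polarity: str
    peaks: list[tuple[float, float]]
    precursor_mz: Optional[float] = None
    collision_energy_ev: Optional[float] = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def tic(self) -> float:
        return float(sum(i for _, i in self.peaks))


@dataclass
class FeatureRecord:
    """One MS1 feature: a (m/z, RT) pair with an intensity and polarity."""

    feature_id: str
    mz: float
    rt_min: float
    intensity: float
    polarity: str
    charge: Optional[int] = None

    def validate(self) -> list[str]:
        problems = []
        if not self.mz > 0:
            problems.append(f"mz must be > 0, got {self.mz}")
        if self.rt_min < 0:
            problems.append(f"rt_min must be >= 0, got {self.rt_min}")
        if not self.intensity > 0:
            problems.append(f"intensity must be > 0, got {self.intensity}")
        if self.polarity not in (POSITIVE, NEGATIVE):
            problems.append(f"polarity must be positive/negative, got {self.polarity!r}")
        return problems


QUANTIFIER = "quantifier"
QUALIFIER = "qualifier"


@dataclass
class TransitionRow:
    """One row of the output transition table.

    ``role`` distinguishes the quantifier (used for quantitation; exactly
    one per compound) from qualifier transitions that confirm identity.
    ``rt_window_min`` is the scheduling half-width around ``rt_min``.
    """

    compound_label: str
    precursor_mz: float
    fragment_mz: float
    polarity: str
    collision_energy_ev: float
    rt_min: float
    rt_window_min: float
    role: str
    peak_area: Optional[float] = None

    def validate(self) -> list[str]:
        problems = []
        if self.collision_energy_ev < 5.0:
            problems.append(
                f"collision energy {self.collision_energy_ev} eV below the 5 eV floor"
            )
        if not self.rt_window_min > 0:
            problems.append(f"rt_window_min must be > 0, got {self.rt_window_min}")
        if self.role not in (QUANTIFIER, QUALIFIER):
            problems.append(f"role must be quantifier/qualifier, got {self.role!r}")
        if self.polarity not in (POSITIVE, NEGATIVE):
            problems.append(f"polarity must be positive/negative, got {self.polarity!r}")
        return problems


def validate_transition_rows(rows: list[TransitionRow]) -> list[str]:
    """Validate a full table: per-row invariants plus the one-quantifier rule."""
    problems: list[str] = []
    quant_counts: dict[str, int] = {}
    for i, row in enumerate(rows):
        for p in row.validate():
            problems.append(f"row {i} ({row.compound_label}): {p}")
        if row.role == QUANTIFIER:
            quant_counts[row.compound_label] = quant_counts.get(row.compound_label, 0) + 1
        else:
            quant_counts.setdefault(row.compound_label, 0)
    for label, n in quant_counts.items():
        if n != 1:
            problems.append(f"compound {label!r} has {n} quantifier rows (expected 1)")
    return problems
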