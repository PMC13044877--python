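"""Simple quantitation utilities for acquired transition chromatograms.

MRM quantitation integrates the chromatographic peak of each transition.
This module provides exactly the trapezoidal integrator needed to close
the loop on synthetic data; it is not a replacement for vendor peak
integration of real acquisitions (no baseline model, no peak-shape fit).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def trapezoidal_peak_area(
    times_min: Sequence[float],
    intensities: Sequence[float],
    rt_center_min: Optional[float] = None,
    half_width_min: Optional[float] = None,
) -> float:
    """Trapezoidal area of a transition chromatogram.

    When ``rt_center_min``/``half_width_min`` are given, integration is
    restricted to the scheduling window [center − hw, center + hw];
    otherwise the full trace is integrated.  Returns 0.0 for traces with
    fewer than two points in the window.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and intensities must have the same length")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if rt_center_min is not None and half_width_min is not None:
        mask = np.abs(t - rt_center_min) <= half_width_min
        t, y = t[mask], y[mask]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(y, t))
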