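"""Collision-energy optimization by interpolating-spline argmax.

Each fragment's collision-energy–intensity profile, sampled at up to four
discrete energies (0/10/20/40 eV), is fit with a univariate interpolating
spline (smoothing 0 — the curve passes through every observed point;
default degree 2).  The optimal collision energy is the argmax of the
fitted curve over the observed energy span, located by dense grid search
refined with bounded local maximization.  Predictions below 5 eV — the
lower operational limit of standard triple-quadrupole instruments — are
clamped to 5 eV, and the argmax search never trusts spline excursions
outside the sampled span.  Profiles observed at fewer than three energies
fall back to the observed energy of maximal intensity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.optimize import minimize_scalar

from .config import SplineConfig
from .fragment_profiles import CEProfile

SPLINE_ARGMAX = "spline_argmax"
OBSERVED_FALLBACK = "observed_fallback"
CLAMPED_FLOOR = "clamped_floor"


@dataclass
class CEPrediction:
    """Optimized collision energy for one precursor–fragment pair."""

    profile: CEProfile
    fitted: bool
    ce_opt_ev: float
    predicted_max_intensity: float
    method: str


def fit_profile_spline(profile: CEProfile, cfg: SplineConfig | None = None):
    """Return the interpolating spline over a profile's observed points.

    Degree is capped at ``n_points − 1`` so three observations still
    admit the default quadratic fit.
    """
    cfg = cfg or SplineConfig()
    obs = profile.fragment.observations
    ces = np.array(sorted(obs))
    intens = np.array([obs[ce] for ce in ces])
    k = min(cfg.spline_degree, len(ces) - 1)
    # InterpolatedUnivariateSpline is the s=0 case: passes through every point
    return InterpolatedUnivariateSpline(ces, intens, k=k)


def fit_ce_spline(profile: CEProfile, cfg: SplineConfig | None = None) -> CEPrediction:
    """Fit the spline and locate the optimal CE for a ≥3-energy profile.

    The argmax is searched over [min observed CE, max observed CE] on a
    grid (default 0.1 eV) and refined by bounded scalar maximization in
    the bracketing interval.  Results below the 5 eV floor are clamped,
    recorded as ``clamped_floor``.
    """
    cfg = cfg or SplineConfig()
    obs = profile.fragment.observations
    if len(obs) < 3:
        raise ValueError("spline fit requires observations at >= 3 collision energies")
    spline = fit_profile_spline(profile, cfg)
    lo, hi = min(obs), max(obs)
    grid = np.arange(lo, hi + cfg.grid_step_ev / 2, cfg.grid_step_ev)
    vals = spline(grid)
    i = int(np.argmax(vals))
    # refine within the bracketing grid cell(s)
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    ce_opt = float(grid[i])
    peak_val = float(vals[i])
    if b > a:
        res = minimize_scalar(lambda x: -spline(x), bounds=(a, b), method="bounded")
        if res.success and -res.fun >= peak_val:
            ce_opt = float(res.x)
            peak_val = float(-res.fun)
    if cfg.ce_adjust_fn is not None:
        ce_opt = float(cfg.ce_adjust_fn(ce_opt))
    method = SPLINE_ARGMAX
    if ce_opt < cfg.ce_floor_ev:
        ce_opt = cfg.ce_floor_ev
        method = CLAMPED_FLOOR
    elif ce_opt > cfg.ce_ceiling_ev:
        ce_opt = cfg.ce_ceiling_ev
        method = CLAMPED_FLOOR
    return CEPrediction(
        profile=profile,
        fitted=True,
        ce_opt_ev=ce_opt,
        predicted_max_intensity=peak_val,
        method=method,
    )


def fallback_ce(profile: CEProfile, cfg: SplineConfig | None = None) -> CEPrediction:
    """Optimal CE for sparse profiles: the observed energy of maximal intensity.

    Profiles seen at only one or two energies still yield a usable
    transition at the energy where the fragment was actually observed,
    clamped to the 5 eV floor.
    """
    cfg = cfg or SplineConfig()
    obs = profile.fragment.observations
    if not obs:
        raise ValueError("cannot derive a collision energy from an empty profile")
    ce_best = max(obs, key=lambda ce: (obs[ce], -ce))
    return CEPrediction(
        profile=profile,
        fitted=False,
        ce_opt_ev=max(float(ce_best), cfg.ce_floor_ev),
        predicted_max_intensity=float(obs[ce_best]),
        method=OBSERVED_FALLBACK,
    )


def predict_ce(profile: CEProfile, cfg: SplineConfig | None = None) -> CEPrediction:
    """Dispatch to the spline fit or the observed-CE fallback by coverage."""
    if profile.fragment.n_energies >= 3:
        return fit_ce_spline(profile, cfg)
    return fallback_ce(profile, cfg)
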