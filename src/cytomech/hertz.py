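"""Hertz spherical-indentation model: forward force curves and modulus fitting.

A rigid sphere of radius ``R_tip`` indenting an elastic half-space by a
depth ``δ`` produces the force

    F(δ) = (4/3) · E/(1 − ν²) · √R_tip · δ^(3/2)

where ``E`` is the Young's modulus of the sample and ``ν`` its Poisson
ratio (0.5 for an incompressible cell).  A measured AFM force curve also
contains a pre-contact baseline and an unknown contact point, so the fit
estimates ``(E, contact offset, baseline)`` jointly: a grid search over
candidate contact points (each solved by linear least squares in the
amplitude and baseline) picks the basin, and a joint nonlinear refinement
polishes all three parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["ForceCurve", "HertzFit", "hertz_force", "fit_hertz"]


@dataclass
class ForceCurve:
    """Single force–indentation record for one cell.

    ``z`` is the indentation axis in metres, increasing toward the sample;
    the contact point may sit anywhere along it.  ``force`` is in newtons.
    """

    z: np.ndarray
    force: np.ndarray
    tip_radius: float  # m
    cell_id: str = ""
    approach_velocity: float | None = None  # m/s, informational

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape:
            raise ValueError("z and force must have the same length")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")


@dataclass
class HertzFit:
    """Result of fitting the Hertz model to one force curve."""

    modulus: float | None  # Pa
    poisson_ratio: float
    contact_offset: float | None  # m, along the z axis
    baseline: float | None  # N
    rss: float
    r_squared: float
    converged: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


def hertz_force(
    modulus: float,
    poisson_ratio: float,
    tip_radius: float,
    indentation: float | np.ndarray,
) -> float | np.ndarray:
    """Hertz force for a sphere indenting an elastic half-space."""
    delta = np.asarray(indentation, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if modulus <= 0 or tip_radius <= 0:
        raise ValueError("modulus and tip radius must be positive")
    amp = 4.0 / 3.0 * modulus / (1.0 - poisson_ratio**2) * math.sqrt(tip_radius)
    out = amp * delta**1.5
    return float(out) if np.isscalar(indentation) else out


def _amplitude_to_modulus(amp: float, poisson_ratio: float, tip_radius: float) -> float:
    return amp * 0.75 * (1.0 - poisson_ratio**2) / math.sqrt(tip_radius)


def _linear_fit_at_contact(
    z: np.ndarray, f: np.ndarray, z_c: float
) -> tuple[float, float, float]:
    """Best (baseline, amplitude, rss) for a fixed contact point z_c."""
    delta = np.clip(z - z_c, 0.0, None)
    basis = delta**1.5
    design = np.column_stack([np.ones_like(z), basis])
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    resid = f - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_hertz(
    curve: ForceCurve,
    poisson_ratio: float = 0.5,
    fit_fraction: float = 1.0,
    n_grid: int = 100,
    min_contrast: float = 0.2,
) -> HertzFit:
    """Fit the Hertz model with joint contact-point estimation.

    ``fit_fraction`` restricts the fitted region to indentations up to that
    fraction of the maximum indentation past the estimated contact point
    (thin samples violate the half-space assumption at deep indentation).
    A curve is declared non-converged when adding the Hertz term explains
    less than ``min_contrast`` of the baseline-only residual variance —
    the signature of a curve with no detectable contact.
    """
    if not 0.0 < fit_fraction <= 1.0:
        raise ValueError("fit fraction must lie in (0, 1]")
    z, f = curve.z, curve.force
    if len(z) < 10:
        raise ValueError("force curve too short to fit")

    order = np.argsort(z)
    z, f = z[order], f[order]

    # grid over candidate contact points in the lower 90% of the z range
    z_lo, z_hi = z[0], z[0] + 0.9 * (z[-1] - z[0])
    candidates = np.linspace(z_lo, z_hi, n_grid)
    fits = [_linear_fit_at_contact(z, f, zc) for zc in candidates]
    rss = np.array([fit[2] for fit in fits])
    amps = np.array([fit[1] for fit in fits])
    valid = amps > 0
    if not np.any(valid):
        return HertzFit(None, poisson_ratio, None, None, float(rss.min()),
                        float("nan"), converged=False)
    best = int(np.flatnonzero(valid)[np.argmin(rss[valid])])
    z_c0 = float(candidates[best])
    b0, a0, _ = fits[best]

    # dimensionless parameters (z_c/span, baseline/f_scale, log amplitude)
    # keep the numerical Jacobian well conditioned
    span = z[-1] - z[0]
    f_scale = max(float(np.abs(f).max()), 1e-30)

    def residuals(x: np.ndarray) -> np.ndarray:
        z_c = z[0] + x[0] * span
        b = x[1] * f_scale
        delta = np.clip(z - z_c, 0.0, None)
        return (b + math.exp(x[2]) * delta**1.5 - f) / f_scale

    refine = least_squares(
        residuals,
        x0=[(z_c0 - z[0]) / span, b0 / f_scale, math.log(max(a0, 1e-30))],
        bounds=([-0.1, -np.inf, -90.0], [1.0, np.inf, 90.0]),
        xtol=1e-14,
        ftol=1e-14,
    )
    z_c = float(z[0] + refine.x[0] * span)
    baseline = float(refine.x[1] * f_scale)
    amp = math.exp(refine.x[2])

    # optionally restrict the indentation range and re-refine
    if fit_fraction < 1.0:
        delta_max = max(z[-1] - z_c, 0.0)
        keep = z <= z_c + fit_fraction * delta_max
        if keep.sum() >= 10:
            z_fit, f_fit = z[keep], f[keep]

            def residuals_frac(x: np.ndarray) -> np.ndarray:
                zc = z[0] + x[0] * span
                b = x[1] * f_scale
                delta = np.clip(z_fit - zc, 0.0, None)
                return (b + math.exp(x[2]) * delta**1.5 - f_fit) / f_scale

            refine = least_squares(
                residuals_frac,
                x0=refine.x,
                bounds=([-0.1, -np.inf, -90.0], [1.0, np.inf, 90.0]),
                xtol=1e-14,
                ftol=1e-14,
            )
            z_c = float(z[0] + refine.x[0] * span)
            baseline = float(refine.x[1] * f_scale)
            amp = math.exp(refine.x[2])
            z, f = z_fit, f_fit

    model = baseline + amp * np.clip(z - z_c, 0.0, None) ** 1.5
    rss_full = float(np.sum((model - f) ** 2))
    rss_base = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - rss_full / rss_base if rss_base > 0 else float("-inf")
    contrast = 1.0 - rss_full / rss_base if rss_base > 0 else 0.0
    converged = bool(refine.success) and contrast >= min_contrast
    modulus = _amplitude_to_modulus(amp, poisson_ratio, curve.tip_radius)
    return HertzFit(
        modulus if converged else None,
        poisson_ratio,
        z_c if converged else None,
        baseline if converged else None,
        rss=rss_full,
        r_squared=r2,
        converged=converged,
    )
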