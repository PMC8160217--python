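"""Flow scaling inside the evaporating droplet and front kinematics.

Phase-separated dextran-rich compartments are observed to move *inward*,
against the outward capillary ("coffee-ring") flow that edge-enhanced
evaporation would drive.  The explanation is a Marangoni flow: PEG is surface
active, so the composition jump produced by phase separation at the rim lowers
the local surface tension and pulls the interface (and the compartments
beneath it) towards the droplet center.  This module provides the scaling
quantities behind that argument:

* the Bond number ``rho g R^2 / gamma`` (surface tension dominates gravity
  when it is small),
* the depth-averaged outward capillary velocity obtained from liquid mass
  conservation under the non-uniform evaporation flux,
* the lubrication-approximation Marangoni velocity scale and the surface
  tension difference required to match/reverse the capillary flow -- either by
  inverting the velocity balance directly, or (the default) by balancing the
  Marangoni stress against the spherical-cap capillary pressure over the film
  thickness, which is the balance that sets the ~mN/m scale,
* the kinematics of the phase-separation front (PSF): front detection on radial
  intensity profiles and a linear fit R2(t) = R2(0) - v t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import quad

from evapollps.errors import DomainError, NumericalError
from evapollps.evaporation import (
    AmbientConditions,
    DropletGeometry,
    local_evaporation_flux,
    total_evaporation_rate,
)

__all__ = [
    "FluidProperties",
    "FrontTrace",
    "LinearFrontFit",
    "bond_number",
    "capillary_velocity_scale",
    "detect_front",
    "marangoni_velocity_scale",
    "psf_linear_fit",
    "required_delta_gamma",
]

STANDARD_GRAVITY = 9.8  # m s^-2


@dataclass(frozen=True)
class FluidProperties:
    """Bulk liquid properties of the droplet solution.

    ``surface_tension_ref`` is gamma at ``surface_tension_ref_w_peg``;
    ``surface_tension_slope`` (N/m per unit mass fraction, negative: PEG is a
    surface-active agent) makes gamma(w_peg) linear around that reference.
    Defaults: gamma = 64 mN/m at the 5 wt% PEG droplet composition, slope
    -70 mN/m per unit w_peg.
    """

    density: float = 1030.0
    viscosity: float = 0.01
    surface_tension_ref: float = 64e-3
    surface_tension_ref_w_peg: float = 0.05
    surface_tension_slope: float = -70e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("density and viscosity must be > 0")
        if self.surface_tension_ref <= 0:
            raise DomainError("surface tension must be > 0")
        if self.surface_tension_slope >= 0:
            raise DomainError("surface tension must decrease with w_peg")

    def surface_tension(self, w_peg: float) -> float:
        """gamma(w_peg), linear model around the calibration point."""
        gamma = self.surface_tension_ref + self.surface_tension_slope * (
            w_peg - self.surface_tension_ref_w_peg
        )
        if gamma <= 0:
            raise DomainError(f"surface-tension model went nonpositive at w_peg={w_peg}")
        return gamma


def bond_number(
    fluid: FluidProperties,
    geom: DropletGeometry,
    g: float = STANDARD_GRAVITY,
) -> float:
    """Bond number Bo = rho g R^2 / gamma with R the contact radius."""
    return fluid.density * g * geom.contact_radius**2 / fluid.surface_tension_ref


def _height_rate(geom: DropletGeometry, r: np.ndarray, dtheta_dt: float) -> np.ndarray:
    """dh/dt at radius r for a pinned cap with contact angle changing at dtheta_dt."""
    a = geom.contact_radius
    th = geom.contact_angle
    rs = a / np.sin(th)
    root = np.sqrt(np.maximum(rs**2 - r**2, 0.0))
    # dh/dtheta = -(a^2 cos th / sin^3 th)/sqrt(Rs^2-r^2) + a/sin^2 th
    dh_dtheta = -(a**2 * np.cos(th) / np.sin(th) ** 3) / root + a / np.sin(th) ** 2
    return dh_dtheta * dtheta_dt


def _cap_volume_dtheta(geom: DropletGeometry) -> float:
    """dV/dtheta of the spherical cap at fixed contact radius (analytic)."""
    a, th = geom.contact_radius, geom.contact_angle
    c, s = np.cos(th), np.sin(th)
    # V = pi a^3/3 * (2 - 3c + c^3)/s^3; differentiate the bracket
    num = 2.0 - 3.0 * c + c**3
    dnum = 3.0 * s - 3.0 * c**2 * s
    return np.pi * a**3 / 3.0 * (dnum * s**3 - num * 3.0 * s**2 * c) / s**6


def capillary_velocity_scale(
    geom: DropletGeometry,
    ambient: AmbientConditions,
    fluid: FluidProperties,
    eval_r: float | None = None,
) -> float:
    """Depth-averaged outward radial velocity of the evaporation-driven flow.

    Mass conservation in the pinned cap gives

        u(r) = 1/(rho r h(r)) * int_0^r [J(r') - rho dh/dt(r')] r' dr'

    with ``J`` the edge-divergent evaporation flux and ``dh/dt`` the uniform
    cap-thinning rate implied by the total evaporation rate.  Positive values
    are outward (towards the rim); the edge-peaked flux makes the flow outward
    near the rim -- the coffee-ring flow the Marangoni stress must beat.

    Evaluated at ``eval_r`` (default 0.95 R0; the rim itself is singular).
    """
    a = geom.contact_radius
    if eval_r is None:
        eval_r = 0.95 * a
    if not 0 < eval_r < a:
        raise DomainError("eval_r must lie in (0, contact_radius)")
    h_eval = float(geom.height_profile(eval_r))
    if h_eval < 1e-4 * geom.cap_height:
        raise NumericalError("eval_r too close to the rim: film thickness ~ 0")
    rate = total_evaporation_rate(geom, ambient)
    dvol_dt = -rate / fluid.density
    dtheta_dt = dvol_dt / _cap_volume_dtheta(geom)

    def integrand(r):
        j = local_evaporation_flux(r, geom, ambient)
        return (j - fluid.density * _height_rate(geom, np.asarray(r), dtheta_dt)) * r

    integral, err = quad(integrand, 0.0, eval_r, limit=200)
    if err > 1e-3 * max(abs(integral), 1e-30):
        raise NumericalError("capillary velocity quadrature did not converge")
    return integral / (fluid.density * eval_r * h_eval)


def marangoni_velocity_scale(
    delta_gamma: float,
    geom: DropletGeometry,
    fluid: FluidProperties,
    gradient_length: float | None = None,
    eval_r: float | None = None,
    *,
    coefficient: float = 0.5,
) -> float:
    """Lubrication-approximation Marangoni velocity scale.

    u_M = coefficient * delta_gamma * h(eval_r) / (mu * gradient_length)

    with the film thickness evaluated at the same radius as the capillary
    scale (default 0.95 R0) and the surface-tension difference acting over
    ``gradient_length`` (default the contact radius).
    """
    a = geom.contact_radius
    if gradient_length is None:
        gradient_length = a
    if gradient_length <= 0:
        raise DomainError("gradient_length must be > 0")
    if eval_r is None:
        eval_r = 0.95 * a
    h_eval = float(geom.height_profile(eval_r))
    return coefficient * delta_gamma * h_eval / (fluid.viscosity * gradient_length)


def required_delta_gamma(
    geom: DropletGeometry,
    ambient: AmbientConditions,
    fluid: FluidProperties,
    gradient_length: float | None = None,
    eval_r: float | None = None,
    *,
    balance: str = "pressure",
    coefficient: float = 0.5,
) -> float:
    """Surface-tension difference needed for Marangoni flow to rival capillarity.

    Two balances are offered:

    ``balance="pressure"`` (default): set the Marangoni stress
    ``delta_gamma / L`` against the capillary-pressure-driven film stress,
    i.e. ``delta_gamma = coefficient * h(eval_r) * DeltaP`` with
    ``DeltaP = 2 gamma sin(theta) / a`` the spherical-cap Laplace pressure.
    This is the lubrication balance that produces the ~mN/m magnitude needed
    to reverse the coffee-ring flow in a millimetric droplet.

    ``balance="velocity"``: exact inversion of
    :func:`marangoni_velocity_scale` at the value of
    :func:`capillary_velocity_scale` -- delta_gamma such that the two velocity
    scales match.  This is typically far smaller, because the evaporation-driven
    depth-averaged velocity is slow compared to the stress scales involved.
    """
    a = geom.contact_radius
    if eval_r is None:
        eval_r = 0.95 * a
    if gradient_length is None:
        gradient_length = a
    h_eval = float(geom.height_profile(eval_r))
    if balance == "pressure":
        laplace = 2.0 * fluid.surface_tension_ref * np.sin(geom.contact_angle) / a
        return coefficient * h_eval * laplace
    if balance == "velocity":
        u_cap = capillary_velocity_scale(geom, ambient, fluid, eval_r)
        # invert u_M = coefficient * dg * h / (mu L) at u_M = u_cap
        return u_cap * fluid.viscosity * gradient_length / (coefficient * h_eval)
    raise DomainError(f"unknown balance {balance!r}; use 'pressure' or 'velocity'")


def achievable_delta_gamma(fluid: FluidProperties, w_peg_a: float, w_peg_b: float) -> float:
    """|gamma(w_peg_a) - gamma(w_peg_b)| from the surface-tension model.

    Evaluated across the composition jump that phase separation creates at the
    rim (e.g. the PEG-poor dextran-rich phase against the initial mixture).
    """
    return abs(fluid.surface_tension(w_peg_a) - fluid.surface_tension(w_peg_b))


@dataclass
class FrontTrace:
    """Phase-separation front radius R2 versus time."""

    times: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.times.shape != self.r2.shape:
            raise DomainError("times and r2 must have the same shape")
        if np.any(self.r2 <= 0):
            raise DomainError("front radii must be positive")

    def displacement(self, contact_radius: float) -> np.ndarray:
        """L(t) = R - R2(t)."""
        return contact_radius - self.r2


@dataclass(frozen=True)
class LinearFrontFit:
    """OLS fit R2(t) = R2_at_0 - v t."""

    v: float
    r2_at_0: float
    r_squared: float
    v_stderr: float


def psf_linear_fit(trace: FrontTrace) -> LinearFrontFit:
    """Least-squares linear fit of the front radius against time.

    The front of the phase-separated region advances inward linearly
    (L ~ t, a flow-driven kinematics rather than the diffusive t^1/2),
    so a straight line is the model; ``v = -slope`` is the inward front speed.
    """
    if len(trace.times) < 3:
        raise DomainError("need at least 3 front records for a linear fit")
    res = stats.linregress(trace.times, trace.r2)
    return LinearFrontFit(
        v=float(-res.slope),
        r2_at_0=float(res.intercept),
        r_squared=float(res.rvalue**2),
        v_stderr=float(res.stderr),
    )


def detect_front(
    r: np.ndarray,
    intensity: np.ndarray,
    *,
    smooth_window: int = 9,
    mode: str = "threshold",
    amp_snr: float = 3.0,
    jump_fraction: float = 0.7,
) -> float | None:
    """Locate the phase-separation front on a radial intensity profile.

    The profile is smoothed with a centered moving average; the candidate front
    is the outermost maximizer of the absolute radial gradient.  Two no-front
    gates reject featureless profiles: the smoothed amplitude must exceed
    ``amp_snr`` times the point-noise scale (estimated from first differences),
    and the intensity jump between the plateaus on either side of the candidate
    must account for at least ``jump_fraction`` of the total amplitude (for a
    featureless linear ramp that ratio is exactly 0.5, so the default 0.7
    rejects ramps and pure noise even when their largest gradient is sizable).

    ``mode="threshold"`` (default) refines the candidate to the outermost
    crossing of the local plateau midpoint, linearly interpolated -- robust to
    sub-sample accuracy for sigmoidal fronts.  ``mode="gradient"`` returns the
    raw max-gradient sample.

    Returns the front radius, or ``None`` when no front is present.
    """
    r = np.asarray(r, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if r.shape != intensity.shape or r.ndim != 1:
        raise DomainError("r and intensity must be 1-D arrays of equal length")
    if len(r) < max(smooth_window, 5):
        raise DomainError("profile too short for front detection")
    if not np.all(np.isfinite(intensity)):
        raise DomainError("intensity must be finite")
    if mode not in ("threshold", "gradient"):
        raise DomainError(f"unknown mode {mode!r}")
    order = np.argsort(r)
    r, intensity = r[order], intensity[order]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(intensity, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")[: len(intensity)]
    else:
        smoothed = intensity
    amp = smoothed.max() - smoothed.min()
    scale = max(np.abs(smoothed).max(), 1e-300)
    # noise scale from raw first differences (robust to the front itself)
    sigma = np.median(np.abs(np.diff(intensity))) / 0.954
    if amp < amp_snr * sigma or amp < 1e-12 * scale:
        return None
    grad = np.abs(np.gradient(smoothed, r))
    peak = grad.max()
    candidates = np.nonzero(grad >= peak * (1 - 1e-12))[0]
    idx = int(candidates[-1])  # outermost maximizer
    # localized-jump gate: fixed-length plateau windows flanking the candidate
    # (fixed length keeps any residual localization bias independent of where
    # the front sits, so it cancels out of a linear R2(t) fit)
    dx = r[1] - r[0]
    width = max(smooth_window, 3) * dx
    win = max(smooth_window, 5) * dx
    inner = smoothed[(r < r[idx] - width) & (r >= r[idx] - width - win)]
    outer = smoothed[(r > r[idx] + width) & (r <= r[idx] + width + win)]
    if len(inner) == 0:
        inner = smoothed[r < r[idx] - width]
    if len(outer) == 0:
        outer = smoothed[r > r[idx] + width]
    m_in = float(np.median(inner)) if len(inner) else float(smoothed[0])
    m_out = float(np.median(outer)) if len(outer) else float(smoothed[-1])
    if abs(m_out - m_in) < jump_fraction * amp:
        return None
    if mode == "gradient":
        return float(r[idx])
    mid = 0.5 * (m_in + m_out)
    above = (smoothed >= mid) if m_out > m_in else (smoothed <= mid)
    crossings = np.nonzero(above[1:] != above[:-1])[0]
    if len(crossings) == 0:
        return float(r[idx])
    i = int(crossings[-1])
    denom = smoothed[i + 1] - smoothed[i]
    frac = 0.5 if denom == 0 else (mid - smoothed[i]) / denom
    return float(r[i] + np.clip(frac, 0.0, 1.0) * (r[i + 1] - r[i]))
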