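"""Diffusion-limited evaporation of a pinned sessile spherical-cap droplet.

A small droplet resting on a plate evaporates at a rate limited by diffusion of
water vapor away from its surface.  For a spherical cap of contact radius ``R``
and contact angle ``theta`` the total water-mass loss rate is

    dM/dt = -pi * R * D * (n_s - n_inf) * f(theta)

where ``D`` is the vapor diffusivity, ``n_s`` and ``n_inf`` the saturated and
ambient vapor mass concentrations, and ``f(theta)`` a purely geometric
contact-angle factor given by an integral representation (evaluated here by
quadrature).  Two closed-form anchors pin the factor down: a hemisphere
(``theta = pi/2``) evaporates like an isolated sphere half, ``f = 2``, and a
flat disk (``theta -> 0``) like a charged disk in the electrostatic analogy,
``f = 4/pi``.

The local evaporation flux diverges towards the pinned contact line.  We adopt
the edge scaling ``J(r) ~ (R0 - r)**-0.5`` over the whole footprint and fix the
prefactor so the disk integral reproduces the total rate; the edge annulus,
which is all the downstream phase-separation analysis uses, is where the
scaling is asymptotically exact.

All quantities are SI internally (m, s, kg, rad).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from evapollps.errors import DomainError, DryOutError, NumericalError

__all__ = [
    "AmbientConditions",
    "DropletGeometry",
    "EvaporationTrace",
    "annulus_liquid_volume",
    "annulus_water_loss",
    "cap_volume",
    "contact_angle_from_volume",
    "contact_angle_factor",
    "contact_radius_from_volume",
    "evolve_droplet",
    "local_evaporation_flux",
    "total_evaporation_rate",
]

#: Density of liquid water near room temperature, kg m^-3.
WATER_DENSITY = 998.0


def cap_volume(contact_radius: float, contact_angle: float) -> float:
    """Volume of a spherical cap with given contact radius and angle.

    V = pi a^3 (2 - 3 cos(theta) + cos(theta)^3) / (3 sin(theta)^3)
    """
    a, th = contact_radius, contact_angle
    c, s = np.cos(th), np.sin(th)
    return np.pi * a**3 * (2.0 - 3.0 * c + c**3) / (3.0 * s**3)


def contact_angle_from_volume(
    contact_radius: float, volume: float, *, theta_max: float = np.pi / 2
) -> float:
    """Invert the spherical-cap volume relation for the contact angle.

    The cap volume is strictly increasing in theta at fixed contact radius, so
    the inversion is a bracketed root-find.
    """
    if volume <= 0:
        raise DomainError(f"volume must be positive, got {volume}")
    lo, hi = 1e-9, theta_max
    f = lambda th: cap_volume(contact_radius, th) - volume
    if f(hi) < 0:
        raise DomainError(
            "volume too large for the requested contact radius and theta_max"
        )
    return brentq(f, lo, hi, xtol=1e-14)


def contact_radius_from_volume(volume: float, contact_angle: float) -> float:
    """Contact radius of a cap with given volume and contact angle."""
    c, s = np.cos(contact_angle), np.sin(contact_angle)
    return (3.0 * volume * s**3 / (np.pi * (2.0 - 3.0 * c + c**3))) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DropletGeometry:
    """Spherical-cap state of a sessile droplet.

    Parameters
    ----------
    contact_radius
        Footprint radius ``a`` on the substrate, m.
    contact_angle
        Contact angle ``theta``, rad.  The flux model requires ``theta < pi/2``
        (the droplets modeled here sit at 25-45 degrees).
    """

    contact_radius: float
    contact_angle: float

    def __post_init__(self) -> None:
        if not self.contact_radius > 0:
            raise DomainError(f"contact_radius must be > 0, got {self.contact_radius}")
        if not 0 < self.contact_angle < np.pi / 2:
            raise DomainError(
                "contact_angle must lie in (0, pi/2) for the flux model, "
                f"got {self.contact_angle}"
            )

    @classmethod
    def from_volume(
        cls, volume: float, contact_angle: float
    ) -> "DropletGeometry":
        """Build a geometry from droplet volume (m^3) and contact angle."""
        return cls(contact_radius_from_volume(volume, contact_angle), contact_angle)

    @property
    def sphere_radius(self) -> float:
        """Radius of the sphere the cap is cut from: a / sin(theta)."""
        return self.contact_radius / np.sin(self.contact_angle)

    @property
    def cap_height(self) -> float:
        """Apex height h(0) = a tan(theta/2)."""
        return self.contact_radius * np.tan(self.contact_angle / 2.0)

    @property
    def cap_volume(self) -> float:
        return cap_volume(self.contact_radius, self.contact_angle)

    def height_profile(self, r):
        """Liquid height h(r) above the substrate, for 0 <= r <= contact_radius."""
        r = np.asarray(r, dtype=float)
        if np.any(r < 0) or np.any(r > self.contact_radius * (1 + 1e-12)):
            raise DomainError("r must lie in [0, contact_radius]")
        rs = self.sphere_radius
        h = np.sqrt(np.maximum(rs**2 - r**2, 0.0)) - rs * np.cos(self.contact_angle)
        return np.maximum(h, 0.0)


@dataclass(frozen=True)
class AmbientConditions:
    """Vapor-side conditions governing diffusion-limited evaporation.

    ``vapor_diffusivity`` (m^2 s^-1), ``saturated_vapor_concentration`` and
    ``ambient_vapor_concentration`` (kg m^-3).  Construct from relative
    humidity with :meth:`from_relative_humidity`.
    """

    vapor_diffusivity: float
    saturated_vapor_concentration: float
    ambient_vapor_concentration: float

    def __post_init__(self) -> None:
        if not self.vapor_diffusivity > 0:
            raise DomainError("vapor_diffusivity must be > 0")
        if not 0 <= self.ambient_vapor_concentration <= self.saturated_vapor_concentration:
            raise DomainError(
                "ambient vapor concentration must lie in [0, saturated]"
            )

    @classmethod
    def from_relative_humidity(
        cls,
        relative_humidity: float,
        vapor_diffusivity: float = 2.5e-5,
        saturated_vapor_concentration: float = 2.3e-2,
    ) -> "AmbientConditions":
        """Ambient conditions with n_inf = RH * n_s.

        Defaults (D = 2.5e-5 m^2/s, n_s = 2.3e-2 kg/m^3) are textbook values
        for water vapor in air near 22 C; they are configuration defaults, not
        measured constants.
        """
        if not 0 <= relative_humidity <= 1:
            raise DomainError("relative_humidity must lie in [0, 1]")
        return cls(
            vapor_diffusivity,
            saturated_vapor_concentration,
            relative_humidity * saturated_vapor_concentration,
        )

    @property
    def relative_humidity(self) -> float:
        return self.ambient_vapor_concentration / self.saturated_vapor_concentration

    @property
    def concentration_difference(self) -> float:
        return self.saturated_vapor_concentration - self.ambient_vapor_concentration


def _factor_integrand(tau: np.ndarray, theta: float) -> np.ndarray:
    """Overflow-safe integrand of the contact-angle factor.

    (1 + cosh 2*theta*tau) / sinh(2*pi*tau) * tanh((pi - theta) tau)
      = exp(-2(pi-theta)tau) (1 + 2 e^{-2 theta tau} + e^{-4 theta tau})
        / (1 - e^{-4 pi tau}) * tanh((pi - theta) tau)

    with the removable singularity at tau = 0 filled by its limit
    (pi - theta)/pi.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.full_like(tau, (np.pi - theta) / np.pi)
    nz = tau > 0
    t = tau[nz]
    num = np.exp(-2.0 * (np.pi - theta) * t) * (
        1.0 + 2.0 * np.exp(-2.0 * theta * t) + np.exp(-4.0 * theta * t)
    )
    den = 1.0 - np.exp(-4.0 * np.pi * t)
    out[nz] = num / den * np.tanh((np.pi - theta) * t)
    return out


def contact_angle_factor(theta: float) -> float:
    """Dimensionless contact-angle factor of diffusion-limited evaporation.

    f(theta) = sin(theta)/(1 + cos(theta))
               + 4 * int_0^inf (1 + cosh 2*theta*tau)/sinh(2*pi*tau)
                              * tanh((pi - theta) tau) dtau

    Anchors: f(pi/2) = 2 (hemisphere) and f -> 4/pi as theta -> 0 (flat disk).

    Parameters
    ----------
    theta
        Contact angle in rad, 0 < theta < pi.
    """
    if not 0 < theta < np.pi:
        raise DomainError(f"theta must lie in (0, pi), got {theta}")
    # The integrand decays like exp(-2 (pi - theta) tau); truncate where it has
    # fallen below ~1e-16 of its tau->0 value.
    tau_max = 20.0 / (np.pi - theta)
    val, err = quad(
        _factor_integrand,
        0.0,
        tau_max,
        args=(theta,),
        epsabs=1e-13,
        epsrel=1e-11,
        limit=200,
    )
    if err > 1e-8 * max(abs(val), 1.0):
        raise NumericalError(
            f"contact-angle-factor quadrature error estimate {err:g} too large "
            f"(theta={theta:g}, value={val:g})"
        )
    return np.sin(theta) / (1.0 + np.cos(theta)) + 4.0 * val


def total_evaporation_rate(geom: DropletGeometry, ambient: AmbientConditions) -> float:
    """Magnitude of the droplet water-mass loss rate, kg s^-1.

    pi * R * D * (n_s - n_inf) * f(theta).
    """
    return (
        np.pi
        * geom.contact_radius
        * ambient.vapor_diffusivity
        * ambient.concentration_difference
        * contact_angle_factor(geom.contact_angle)
    )


def _flux_prefactor(geom: DropletGeometry, ambient: AmbientConditions) -> float:
    """Prefactor C of J(r) = C (R0 - r)^-1/2 normalized to the total rate.

    The disk integral of the power law is analytic:
    int_0^R0 (R0 - r)^{-1/2} 2 pi r dr = (8 pi / 3) R0^{3/2}.
    """
    r0 = geom.contact_radius
    return 3.0 * total_evaporation_rate(geom, ambient) / (8.0 * np.pi * r0**1.5)


def local_evaporation_flux(r, geom: DropletGeometry, ambient: AmbientConditions):
    """Local evaporation flux J(r) = C (R0 - r)^-1/2, kg m^-2 s^-1.

    The inverse-square-root divergence towards the pinned contact line is the
    same integrable singularity that drives the coffee-ring effect; the
    prefactor is fixed so that the flux integrated over the contact disk equals
    :func:`total_evaporation_rate`.
    """
    r = np.asarray(r, dtype=float)
    r0 = geom.contact_radius
    if np.any(r < 0) or np.any(r >= r0):
        raise DomainError("r must lie in [0, contact_radius); the rim is singular")
    return _flux_prefactor(geom, ambient) / np.sqrt(r0 - r)


def _annulus_flux_integral(r0: float, r1: float) -> float:
    """int_{r1}^{R0} (R0 - r)^{-1/2} 2 pi r dr, closed form."""
    u1 = r0 - r1
    return 2.0 * np.pi * (2.0 * r0 * np.sqrt(u1) - (2.0 / 3.0) * u1**1.5)


def annulus_evaporation_rate(
    geom: DropletGeometry, ambient: AmbientConditions, delta_r_fraction: float
) -> float:
    """Water-mass loss rate from the edge annulus [R0(1-dr), R0], kg s^-1."""
    if not 0 < delta_r_fraction < 1:
        raise DomainError("delta_r_fraction must lie in (0, 1)")
    r0 = geom.contact_radius
    r1 = r0 * (1.0 - delta_r_fraction)
    return _flux_prefactor(geom, ambient) * _annulus_flux_integral(r0, r1)


def annulus_liquid_volume(geom: DropletGeometry, delta_r_fraction: float) -> float:
    """Liquid volume under the edge annulus, m^3 (analytic).

    V = int_{r1}^{a} 2 pi r h(r) dr with h(r) the spherical-cap height profile:
    (2 pi / 3) [(Rs^2 - r1^2)^{3/2} - (Rs cos theta)^3]
      - pi Rs cos(theta) (a^2 - r1^2).
    """
    if not 0 < delta_r_fraction < 1:
        raise DomainError("delta_r_fraction must lie in (0, 1)")
    a = geom.contact_radius
    r1 = a * (1.0 - delta_r_fraction)
    rs = geom.sphere_radius
    cz = rs * np.cos(geom.contact_angle)  # height of sphere center below apex plane
    spherical = (2.0 * np.pi / 3.0) * ((rs**2 - r1**2) ** 1.5 - cz**3)
    return spherical - np.pi * cz * (a**2 - r1**2)


def annulus_water_loss(
    geom: DropletGeometry,
    ambient: AmbientConditions,
    delta_r_fraction: float = 0.05,
    delta_t: float = 5.0,
    *,
    water_mass_available: float | None = None,
) -> float:
    """Water mass (kg) evaporated from the edge annulus during ``delta_t``.

    Parameters
    ----------
    delta_r_fraction
        Annulus width as a fraction of the contact radius (default 0.05, the
        standard edge calculation domain).
    delta_t
        Time step, s (default 5 s).
    water_mass_available
        Optional cap: raise :class:`DryOutError` if the evaporated mass would
        exceed it.  When omitted, the cap defaults to the mass of pure water
        filling the annulus volume.
    """
    if delta_t < 0:
        raise DomainError("delta_t must be >= 0")
    loss = annulus_evaporation_rate(geom, ambient, delta_r_fraction) * delta_t
    if water_mass_available is None:
        water_mass_available = WATER_DENSITY * annulus_liquid_volume(
            geom, delta_r_fraction
        )
    if loss > water_mass_available:
        raise DryOutError(
            f"annulus would lose {loss:.3e} kg of water in {delta_t} s but only "
            f"{water_mass_available:.3e} kg is available; use a smaller delta_t"
        )
    return loss


@dataclass
class EvaporationTrace:
    """Time series of a pinned droplet drying down.

    ``times`` (s), ``geometries`` (one per time), ``water_lost`` cumulative kg.
    ``truncated`` flags an early stop at the contact-angle floor.
    """

    times: list[float] = field(default_factory=list)
    geometries: list[DropletGeometry] = field(default_factory=list)
    water_lost: list[float] = field(default_factory=list)
    truncated: bool = False

    def append(self, t: float, geom: DropletGeometry, lost: float) -> None:
        if self.times and t <= self.times[-1]:
            raise DomainError("times must be strictly increasing")
        self.times.append(t)
        self.geometries.append(geom)
        self.water_lost.append(lost)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        """Trace as a pandas DataFrame (time_s, contact_radius_m, ...)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "contact_radius_m": [g.contact_radius for g in self.geometries],
                "contact_angle_rad": [g.contact_angle for g in self.geometries],
                "volume_m3": [g.cap_volume for g in self.geometries],
                "water_lost_kg": self.water_lost,
            }
        )


def evolve_droplet(
    geom0: DropletGeometry,
    ambient: AmbientConditions,
    delta_t: float,
    n_steps: int,
    *,
    water_density: float = WATER_DENSITY,
    theta_floor: float = np.deg2rad(5.0),
) -> EvaporationTrace:
    """Integrate pinned-contact-line drying: fixed footprint, falling angle.

    Each step removes ``total_evaporation_rate * delta_t`` of water mass from
    the cap volume and re-inverts the spherical-cap relation for the new
    contact angle.  Integration stops early (``trace.truncated = True``) if the
    angle would fall below ``theta_floor`` or the volume would go negative.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    if delta_t <= 0:
        raise DomainError("delta_t must be > 0")
    trace = EvaporationTrace()
    geom = geom0
    lost = 0.0
    trace.append(0.0, geom, lost)
    for k in range(1, n_steps + 1):
        dm = total_evaporation_rate(geom, ambient) * delta_t
        new_volume = geom.cap_volume - dm / water_density
        floor_volume = cap_volume(geom.contact_radius, theta_floor)
        if new_volume <= floor_volume:
            trace.truncated = True
            break
        theta = contact_angle_from_volume(geom.contact_radius, new_volume)
        geom = DropletGeometry(geom.contact_radius, theta)
        lost += dm
        trace.append(k * delta_t, geom, lost)
    return trace
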