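"""The PEG/dextran phase plane and the evaporation-driven kinetic pathway.

An aqueous mixture of PEG and dextran demixes into a PEG-rich and a
dextran-rich phase once its composition crosses the binodal curve.  In an
evaporating sessile droplet the crossing happens first in the thin annulus at
the droplet rim, where the evaporation flux diverges.  This module provides:

* the composition plane (``Composition``, axes x = w_dex, y = w_peg, both mass
  fractions),
* a fitted binodal (Merchuk-type empirical curve, or a tabulated monotone
  interpolant),
* tie-line construction and the lever rule,
* the stepwise kinetic pathway: per time step, water evaporated from the edge
  annulus concentrates the local composition along a constant-ratio ray until
  it crosses the binodal, after which every step also records the tie-line
  split (phase compositions and mass fractions) and the tie-line length (TLL,
  the quench-depth measure that grows as drying proceeds),
* regime classification.  Regime 1 (lobe-forming, coalescing dextran-rich
  domains) arises when the first split yields comparable phase masses; regime 2
  (dispersed dextran-rich droplets) when the dextran-rich phase is a small
  minority.  An empirical composition map mirrors the observed pattern diagram:
  below 4 wt% dextran the dispersed regime requires PEG more than twice
  dextran; above it, PEG beyond about 7 wt%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from evapollps.errors import DomainError, DryOutError, FitError, GeometryError
from evapollps.evaporation import (
    AmbientConditions,
    DropletGeometry,
    annulus_liquid_volume,
    annulus_water_loss,
    contact_angle_from_volume,
    total_evaporation_rate,
)

__all__ = [
    "Composition",
    "MerchukBinodal",
    "TabulatedBinodal",
    "TieLine",
    "PhaseSplit",
    "KineticPathway",
    "PathwayStep",
    "fit_binodal",
    "is_two_phase",
    "tie_line_through",
    "lever_rule",
    "tie_line_length",
    "concentrate",
    "kinetic_pathway",
    "classify_regime",
]

#: Default density of the dilute polymer solution, kg m^-3 (config default).
SOLUTION_DENSITY = 1030.0


@dataclass(frozen=True)
class Composition:
    """A point in the (w_dex, w_peg) plane; mass fractions of total solution."""

    w_peg: float
    w_dex: float

    def __post_init__(self) -> None:
        if self.w_peg < 0 or self.w_dex < 0:
            raise DomainError("mass fractions must be nonnegative")
        if self.w_peg + self.w_dex >= 1:
            raise DomainError("polymer fractions must sum to < 1 (some water left)")

    @classmethod
    def from_wt_percent(cls, peg_pct: float, dex_pct: float) -> "Composition":
        return cls(peg_pct / 100.0, dex_pct / 100.0)

    @property
    def w_water(self) -> float:
        return 1.0 - self.w_peg - self.w_dex

    def as_point(self) -> np.ndarray:
        """(w_dex, w_peg) coordinates, matching the phase-diagram axes."""
        return np.array([self.w_dex, self.w_peg])


class _BinodalBase:
    """Common interface: curve(w_dex) -> w_peg over a validity range."""

    validity: tuple[float, float]

    def curve(self, w_dex):  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_range(self, w_dex) -> None:
        lo, hi = self.validity
        w = np.asarray(w_dex, dtype=float)
        if np.any(w < lo - 1e-12) or np.any(w > hi + 1e-12):
            raise DomainError(
                f"w_dex={w_dex} outside binodal validity range [{lo:g}, {hi:g}]"
            )


@dataclass(frozen=True)
class MerchukBinodal(_BinodalBase):
    """Merchuk-type empirical binodal w_peg = a exp(b sqrt(w) + c w + d w^3).

    The four-parameter exponential is the standard empirical fit for
    PEG/dextran-family coexistence curves.  ``validity`` is the w_dex range
    covered by the data; ``rms_log_residual`` summarizes the fit (0 for an
    exactly constructed curve).
    """

    a: float
    b: float
    c: float
    d: float
    validity: tuple[float, float] = (1e-4, 0.35)
    rms_log_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise DomainError("binodal amplitude a must be > 0")
        if not self.is_monotone_decreasing():
            raise FitError("binodal curve is not strictly decreasing on its range")

    def curve(self, w_dex):
        self._check_range(w_dex)
        w = np.asarray(w_dex, dtype=float)
        return self.a * np.exp(self.b * np.sqrt(w) + self.c * w + self.d * w**3)

    def is_monotone_decreasing(self, n_grid: int = 512) -> bool:
        lo, hi = self.validity
        w = np.linspace(max(lo, 1e-9), hi, n_grid)
        # B'(w) = B * (b/(2 sqrt w) + c + 3 d w^2); B > 0 always
        slope = self.b / (2.0 * np.sqrt(w)) + self.c + 3.0 * self.d * w**2
        return bool(np.all(slope < 0))


@dataclass(frozen=True)
class TabulatedBinodal(_BinodalBase):
    """Binodal supplied as a dense table, monotone-cubic interpolated."""

    w_dex: np.ndarray
    w_peg: np.ndarray
    validity: tuple[float, float] = field(init=False)
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w_dex, dtype=float)
        p = np.asarray(self.w_peg, dtype=float)
        order = np.argsort(w)
        w, p = w[order], p[order]
        if np.any(np.diff(w) <= 0):
            raise FitError("tabulated w_dex values must be distinct")
        if np.any(np.diff(p) >= 0):
            raise FitError("tabulated binodal must be strictly decreasing")
        object.__setattr__(self, "w_dex", w)
        object.__setattr__(self, "w_peg", p)
        object.__setattr__(self, "validity", (float(w[0]), float(w[-1])))
        object.__setattr__(self, "_interp", PchipInterpolator(w, p))

    def curve(self, w_dex):
        self._check_range(w_dex)
        return self._interp(np.asarray(w_dex, dtype=float))


def fit_binodal(points, *, validity: tuple[float, float] | None = None) -> MerchukBinodal:
    """Least-squares fit of the Merchuk curve to (w_dex, w_peg) pairs.

    The model is log-linear in its parameters
    (ln w_peg = ln a + b sqrt(w) + c w + d w^3), so the fit is a single linear
    least-squares solve; multiplicative measurement noise on w_peg is the
    natural error model in log space.

    Raises :class:`FitError` for fewer than 5 points, repeated w_dex values, or
    a fitted curve that is not strictly decreasing over the validity range.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be an (n, 2) array of (w_dex, w_peg)")
    if len(pts) < 5:
        raise FitError(f"need at least 5 coexistence points, got {len(pts)}")
    w, p = pts[:, 0], pts[:, 1]
    if len(np.unique(w)) != len(w):
        raise FitError("w_dex values must be distinct")
    if np.any(w <= 0) or np.any(p <= 0):
        raise FitError("coexistence points must have positive mass fractions")
    design = np.column_stack([np.ones_like(w), np.sqrt(w), w, w**3])
    coef, *_ = np.linalg.lstsq(design, np.log(p), rcond=None)
    resid = np.log(p) - design @ coef
    if validity is None:
        validity = (float(w.min()), float(w.max()))
    return MerchukBinodal(
        a=float(np.exp(coef[0])),
        b=float(coef[1]),
        c=float(coef[2]),
        d=float(coef[3]),
        validity=validity,
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
    )


def is_two_phase(c: Composition, binodal: _BinodalBase) -> bool:
    """True iff the composition lies strictly above the binodal curve.

    Points exactly on the curve count as single-phase (strict inequality).
    """
    return bool(c.w_peg > binodal.curve(c.w_dex))


@dataclass(frozen=True)
class TieLine:
    """A tie line: the two coexisting phase compositions it connects."""

    peg_rich: Composition
    dex_rich: Composition

    def __post_init__(self) -> None:
        if not (
            self.peg_rich.w_peg > self.dex_rich.w_peg
            and self.dex_rich.w_dex > self.peg_rich.w_dex
        ):
            raise GeometryError(
                "tie-line endpoints must have peg_rich higher in PEG and "
                "dex_rich higher in dextran"
            )

    @property
    def length(self) -> float:
        return tie_line_length(self)


def tie_line_length(tie: TieLine) -> float:
    """Tie-line length: Euclidean distance between endpoints in (w_dex, w_peg)."""
    return float(np.linalg.norm(tie.peg_rich.as_point() - tie.dex_rich.as_point()))


def tie_line_through(
    c: Composition,
    binodal: _BinodalBase,
    tie_slope: float,
    *,
    n_scan: int = 2000,
) -> TieLine:
    """Tie line through a two-phase composition at a fixed slope.

    The line through ``c`` with slope ``tie_slope`` (d w_peg / d w_dex,
    negative for PEG/dextran) is intersected with the binodal by bracketed
    root-finding; the intersection at lower w_dex is the PEG-rich phase, the
    one at higher w_dex the dextran-rich phase.
    """
    if not is_two_phase(c, binodal):
        raise GeometryError("tie_line_through requires a two-phase composition")
    if tie_slope >= 0:
        raise GeometryError("tie slope must be negative in the PEG/dextran plane")
    lo, hi = binodal.validity

    def gap(w):
        return binodal.curve(w) - (c.w_peg + tie_slope * (w - c.w_dex))

    def _bracket_root(w_from: float, w_to: float, pick: str) -> float | None:
        grid = np.linspace(w_from, w_to, n_scan)
        vals = gap(grid)
        sign = np.sign(vals)
        flips = np.nonzero(np.diff(sign) != 0)[0]
        if len(flips) == 0:
            return None
        # take the crossing nearest the bulk composition on each side
        i = flips[-1] if pick == "last" else flips[0]
        return brentq(gap, grid[i], grid[i + 1], xtol=1e-14)

    w_left = _bracket_root(lo, c.w_dex, "last")
    w_right = _bracket_root(c.w_dex, hi, "first")
    if w_left is None or w_right is None:
        raise GeometryError(
            "tie line does not intersect the binodal twice within its validity "
            f"range [{lo:g}, {hi:g}]; composition {c} may be too deep a quench "
            "for the available coexistence data"
        )
    peg_rich = Composition(
        w_peg=float(c.w_peg + tie_slope * (w_left - c.w_dex)), w_dex=float(w_left)
    )
    dex_rich = Composition(
        w_peg=float(max(c.w_peg + tie_slope * (w_right - c.w_dex), 0.0)),
        w_dex=float(w_right),
    )
    return TieLine(peg_rich=peg_rich, dex_rich=dex_rich)


@dataclass(frozen=True)
class PhaseSplit:
    """Lever-rule split of a bulk composition on a tie line."""

    tie_line: TieLine
    mass_fraction_dex_rich: float
    ratio_dex_to_peg: float

    def __post_init__(self) -> None:
        if not 0 <= self.mass_fraction_dex_rich <= 1:
            raise DomainError("mass_fraction_dex_rich must lie in [0, 1]")


def lever_rule(c: Composition, tie: TieLine, *, collinear_tol: float = 1e-6) -> PhaseSplit:
    """Split a bulk composition into its coexisting phases by the lever rule.

    The dextran-rich : PEG-rich mass ratio equals the ratio of distances from
    the bulk point to the PEG-rich and dextran-rich endpoints respectively
    (the phase nearer the bulk point carries more mass).
    """
    p = c.as_point()
    e1 = tie.peg_rich.as_point()
    e2 = tie.dex_rich.as_point()
    seg = e2 - e1
    seg_len = np.linalg.norm(seg)
    if seg_len == 0:
        raise GeometryError("degenerate tie line (coincident endpoints)")
    # distance of the bulk point from the tie-line segment
    t = np.dot(p - e1, seg) / seg_len**2
    perp = np.linalg.norm(p - (e1 + t * seg))
    if perp > collinear_tol or not -1e-12 <= t <= 1 + 1e-12:
        raise GeometryError(
            f"bulk composition is not on the tie-line segment "
            f"(offset {perp:.2e}, parameter {t:.3f})"
        )
    d_peg = np.linalg.norm(p - e1)
    d_dex = np.linalg.norm(p - e2)
    if d_dex == 0:
        frac = 1.0
        ratio = np.inf
    else:
        ratio = d_peg / d_dex
        frac = ratio / (1.0 + ratio)
    return PhaseSplit(tie_line=tie, mass_fraction_dex_rich=float(frac), ratio_dex_to_peg=float(ratio))


def concentrate(c: Composition, water_loss_fraction: float) -> Composition:
    """Remove water: scale both polymer fractions by 1/(1 - fraction).

    ``water_loss_fraction`` is the fraction of the total solution mass removed
    as water.  The PEG:dextran ratio is preserved exactly.
    """
    if water_loss_fraction < 0:
        raise DomainError("water_loss_fraction must be >= 0")
    if water_loss_fraction >= c.w_water:
        raise DryOutError(
            f"cannot remove {water_loss_fraction:.4f} of total mass as water; "
            f"only {c.w_water:.4f} is water"
        )
    scale = 1.0 / (1.0 - water_loss_fraction)
    return Composition(w_peg=c.w_peg * scale, w_dex=c.w_dex * scale)


@dataclass(frozen=True)
class PathwayStep:
    """One time step of the edge-annulus kinetic pathway."""

    step: int
    time: float
    composition: Composition
    two_phase: bool
    split: PhaseSplit | None = None
    tll: float | None = None


@dataclass
class KineticPathway:
    """Time-stamped sequence of edge-annulus compositions and phase splits."""

    steps: list[PathwayStep]
    delta_r_fraction: float
    delta_t: float

    @property
    def first_split(self) -> PathwayStep | None:
        for s in self.steps:
            if s.split is not None:
                return s
        return None

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.steps:
            rows.append(
                {
                    "step": s.step,
                    "time_s": s.time,
                    "w_peg": s.composition.w_peg,
                    "w_dex": s.composition.w_dex,
                    "two_phase": s.two_phase,
                    "ratio_dex_to_peg": s.split.ratio_dex_to_peg if s.split else np.nan,
                    "mass_frac_dex_rich": s.split.mass_fraction_dex_rich
                    if s.split
                    else np.nan,
                    "tll": s.tll if s.tll is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def kinetic_pathway(
    c0: Composition,
    geom: DropletGeometry,
    ambient: AmbientConditions,
    binodal: _BinodalBase,
    tie_slope: float,
    *,
    delta_r_fraction: float = 0.05,
    delta_t: float = 5.0,
    n_steps: int = 10,
    solution_density: float = SOLUTION_DENSITY,
    water_density: float = 998.0,
    stop_after_first_split: bool = False,
    stop_at_dry_out: bool = False,
) -> KineticPathway:
    """Stepwise kinetic pathway of phase separation in the edge annulus.

    Per time step: (i) the analytic annulus integral of the edge-divergent flux
    gives the water mass evaporated from the annulus; (ii) that loss, as a
    fraction of the current annulus liquid mass, concentrates the local
    composition along the constant PEG:dextran ray; (iii) once the composition
    crosses the binodal, the tie line through it and the lever-rule split are
    recorded along with the tie-line length.  Polymers never leave the annulus
    (its liquid mass is reduced only by the evaporated water), and the whole
    droplet geometry is advanced in pinned mode so later steps see the flatter,
    slower-evaporating cap.
    """
    if is_two_phase(c0, binodal):
        raise GeometryError("the droplet must start single-phase")
    steps: list[PathwayStep] = [
        PathwayStep(step=0, time=0.0, composition=c0, two_phase=False)
    ]
    c = c0
    mass = solution_density * annulus_liquid_volume(geom, delta_r_fraction)
    for k in range(1, n_steps + 1):
        available_water = c.w_water * mass
        try:
            dm = annulus_water_loss(
                geom,
                ambient,
                delta_r_fraction,
                delta_t,
                water_mass_available=available_water,
            )
        except DryOutError as exc:
            if stop_at_dry_out:
                break
            raise DryOutError(f"annulus dried out at step {k}: {exc}") from exc
        c = concentrate(c, dm / mass)
        mass -= dm

        # advance the whole droplet (pinned footprint, falling contact angle)
        total_dm = total_evaporation_rate(geom, ambient) * delta_t
        new_volume = geom.cap_volume - total_dm / water_density
        if new_volume > 0:
            theta = contact_angle_from_volume(geom.contact_radius, new_volume)
            geom = DropletGeometry(geom.contact_radius, theta)

        two_phase = is_two_phase(c, binodal)
        split = None
        tll = None
        if two_phase:
            tie = tie_line_through(c, binodal, tie_slope)
            split = lever_rule(c, tie)
            tll = tie_line_length(tie)
        steps.append(
            PathwayStep(
                step=k, time=k * delta_t, composition=c, two_phase=two_phase,
                split=split, tll=tll,
            )
        )
        if stop_after_first_split and split is not None:
            break
    return KineticPathway(steps=steps, delta_r_fraction=delta_r_fraction, delta_t=delta_t)


#: Lever-ratio threshold separating coalescing (regime 1) from dispersed
#: (regime 2) morphologies.  Calibrated so a near-even first split (~1.1)
#: classifies as regime 1 and a strongly asymmetric one (~0.09) as regime 2.
REGIME_RATIO_THRESHOLD = 0.5


def classify_regime(
    c0: Composition,
    *,
    mode: str = "empirical",
    binodal: _BinodalBase | None = None,
    tie_slope: float | None = None,
    geom: DropletGeometry | None = None,
    ambient: AmbientConditions | None = None,
    n_steps: int = 10,
    ratio_threshold: float = REGIME_RATIO_THRESHOLD,
    **pathway_kwargs,
) -> str:
    """Classify the phase-separation pattern regime of an initial composition.

    ``mode="empirical"`` applies the observed composition map directly:
    below 4 wt% dextran the dispersed regime (regime 2) requires PEG more than
    twice dextran; at or above 4 wt% dextran it requires PEG above the ~7 wt%
    critical concentration.  Otherwise the lobe-forming regime 1.

    ``mode="lever_ratio"`` runs the kinetic pathway and thresholds the first
    split's dextran-rich : PEG-rich mass ratio (default threshold 0.5); if no
    split occurs within ``n_steps`` the result is ``"no_llps"``.
    """
    if mode == "empirical":
        peg, dex = c0.w_peg, c0.w_dex
        if dex < 0.04:
            return "regime2" if peg > 2.0 * dex else "regime1"
        return "regime2" if peg > 0.07 else "regime1"
    if mode == "lever_ratio":
        if binodal is None or tie_slope is None or geom is None or ambient is None:
            raise DomainError(
                "lever_ratio mode requires binodal, tie_slope, geom and ambient"
            )
        path = kinetic_pathway(
            c0, geom, ambient, binodal, tie_slope, n_steps=n_steps,
            stop_after_first_split=True, stop_at_dry_out=True, **pathway_kwargs,
        )
        first = path.first_split
        if first is None:
            return "no_llps"
        return (
            "regime1"
            if first.split.ratio_dex_to_peg >= ratio_threshold
            else "regime2"
        )
    raise DomainError(f"unknown mode {mode!r}; use 'empirical' or 'lever_ratio'")
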