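"""Seeded generators emulating the pipeline's external inputs.

Real inputs to the analysis are wet-lab measurements: a coexistence table for
the polymer pair, droplet mass-versus-time weighing data, and radial
fluorescence profiles tracking the phase-separation front.  The generators
here produce statistically realistic stand-ins with known ground truth so that
every downstream stage (binodal fitting, evaporation-rate estimation, front
detection and velocity fitting) can be tested end to end.

Each generator is deterministic given its seed and returns a DataFrame plus a
metadata dict holding the ground truth; ``write_csv`` helpers persist both
(metadata as a JSON sidecar).

Default binodal parameters describe a PEG-8000 / dextran-10000-like pair:
the curve is positioned so the two canonical starting mixtures -- 5 wt% PEG
with 10 wt% dextran, and 9 wt% PEG with 4 wt% dextran -- are single-phase, and
so that edge-annulus evaporation of a 0.5 uL, 45-degree droplet at 60% RH
pushes both across the binodal within the first few 5 s steps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from evapollps.errors import DomainError, FitError
from evapollps.evaporation import AmbientConditions, DropletGeometry, evolve_droplet
from evapollps.phase_kinetics import Composition, MerchukBinodal, tie_line_through

__all__ = [
    "DEFAULT_BINODAL",
    "DEFAULT_TIE_SLOPE",
    "synth_binodal_table",
    "synth_mass_timeseries",
    "synth_front_profiles",
    "write_csv_with_metadata",
]

#: Synthetic PEG-8000/dextran-10000-like binodal (Merchuk parameters).
#: These are package fixtures chosen once, not a measured phase diagram.
DEFAULT_BINODAL = MerchukBinodal(
    a=0.35, b=-5.8, c=2.0, d=-200.0, validity=(0.002, 0.55)
)

#: Largest w_dex worth tabulating (the curve is vanishingly low beyond).
_TABLE_W_DEX_MAX = 0.35

#: Default tie-line slope d(w_peg)/d(w_dex) in the composition plane.
DEFAULT_TIE_SLOPE = -0.55


def write_csv_with_metadata(frame: pd.DataFrame, metadata: dict, path) -> None:
    """Write a CSV plus a ``<name>.meta.json`` sidecar with the ground truth."""
    path = Path(path)
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))


def synth_binodal_table(
    binodal: MerchukBinodal = DEFAULT_BINODAL,
    tie_slope: float = DEFAULT_TIE_SLOPE,
    n_points: int = 40,
    noise_level: float = 0.01,
    seed: int = 0,
    n_tie_lines: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Coexistence table: binodal points plus paired tie-line endpoints.

    Binodal points are sampled log-uniformly in w_dex across the validity
    range (the curve spans decades in w_peg) with multiplicative Gaussian
    noise of relative standard deviation ``noise_level`` on w_peg.  Tie-line
    endpoint pairs (grouped by ``tie_id``) are constructed exactly on the
    noiseless curve through a fan of two-phase compositions.

    Returns (table, metadata); metadata carries the generating parameters.
    """
    if n_points < 5:
        raise FitError("n_points must be >= 5 to support fitting")
    if noise_level < 0:
        raise DomainError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = binodal.validity
    hi = min(hi, _TABLE_W_DEX_MAX)
    w_dex = np.exp(np.linspace(np.log(lo), np.log(hi), n_points))
    w_peg = binodal.curve(w_dex)
    if noise_level > 0:
        w_peg = w_peg * np.exp(rng.normal(0.0, noise_level, size=n_points))
    rows = [
        {"w_dex_wt_pct": 100 * wd, "w_peg_wt_pct": 100 * wp, "tie_id": ""}
        for wd, wp in zip(w_dex, w_peg)
    ]
    # tie lines through progressively deeper quenches along the 1:2 dex:peg ray
    anchors = np.linspace(1.15, 1.8, n_tie_lines)
    base = Composition(w_peg=0.05, w_dex=0.10)
    for k, scale in enumerate(anchors):
        c = Composition(w_peg=base.w_peg * scale, w_dex=base.w_dex * scale)
        tie = tie_line_through(c, binodal, tie_slope)
        for endpoint in (tie.peg_rich, tie.dex_rich):
            rows.append(
                {
                    "w_dex_wt_pct": 100 * endpoint.w_dex,
                    "w_peg_wt_pct": 100 * endpoint.w_peg,
                    "tie_id": f"T{k}",
                }
            )
    frame = pd.DataFrame(rows)
    metadata = {
        "generator": "synth_binodal_table",
        "seed": int(seed),
        "noise_level": float(noise_level),
        "binodal": {"a": binodal.a, "b": binodal.b, "c": binodal.c, "d": binodal.d},
        "validity": list(binodal.validity),
        "tie_slope": float(tie_slope),
    }
    return frame, metadata


def synth_mass_timeseries(
    geom: DropletGeometry,
    ambient: AmbientConditions,
    sigma_rel: float = 0.01,
    n_samples: int = 60,
    seed: int = 0,
    delta_t: float = 5.0,
    liquid_density: float = 998.0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy droplet mass versus time, as a microbalance would record it.

    The noiseless trajectory follows pinned-mode drying; additive Gaussian
    noise with standard deviation ``sigma_rel * initial_mass`` emulates
    weighing error.  Metadata stores the true initial evaporation rate.
    """
    if sigma_rel < 0:
        raise DomainError("sigma_rel must be >= 0")
    rng = np.random.default_rng(seed)
    trace = evolve_droplet(
        geom, ambient, delta_t, n_samples - 1, water_density=liquid_density
    )
    times = np.asarray(trace.times)
    mass0 = liquid_density * geom.cap_volume
    mass = mass0 - np.asarray(trace.water_lost)
    noisy = mass + rng.normal(0.0, sigma_rel * mass0, size=len(mass))
    frame = pd.DataFrame({"time_s": times, "mass_kg": noisy})
    from evapollps.evaporation import total_evaporation_rate

    metadata = {
        "generator": "synth_mass_timeseries",
        "seed": int(seed),
        "sigma_rel": float(sigma_rel),
        "true_initial_rate_kg_per_s": float(total_evaporation_rate(geom, ambient)),
        "initial_mass_kg": float(mass0),
        "contact_radius_m": geom.contact_radius,
        "contact_angle_rad": geom.contact_angle,
        "truncated": trace.truncated,
    }
    return frame, metadata


def synth_front_profiles(
    R0: float,
    v: float = 6e-6,
    times: np.ndarray | None = None,
    front_width: float = 2e-5,
    sigma_rel: float = 0.05,
    seed: int = 0,
    n_radial: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Radial intensity profiles with a linearly advancing front.

    Intensity steps up sigmoidally outside the front radius
    R2(t) = R0 - v t (the phase-separated annulus is the bright region), with
    multiplicative Gaussian noise of relative level ``sigma_rel``.  The default
    inward speed of 6 um/s is the observed phase-separation-front velocity
    scale.  Long-format output: columns time_s, r_m, intensity.

    Raises if any front would exit (0, R0) at the requested times.
    """
    if v < 0:
        raise DomainError("front speed v must be >= 0")
    if times is None:
        times = np.arange(5.0, 65.0, 5.0)
    times = np.asarray(times, dtype=float)
    r2 = R0 - v * times
    bad = times[(r2 <= 0) | (r2 >= R0)]
    if len(bad):
        raise DomainError(f"front exits (0, R0) at times {bad.tolist()}")
    rng = np.random.default_rng(seed)
    r = np.linspace(0.0, R0, n_radial)
    records = []
    for t, front in zip(times, r2):
        if front_width > 0:
            clean = 1.0 + 1.0 / (1.0 + np.exp(-(r - front) / front_width))
        else:
            clean = np.where(r >= front, 2.0, 1.0)
        noisy = clean * np.exp(rng.normal(0.0, sigma_rel, size=n_radial)) if sigma_rel > 0 else clean
        records.append(
            pd.DataFrame({"time_s": t, "r_m": r, "intensity": noisy})
        )
    frame = pd.concat(records, ignore_index=True)
    metadata = {
        "generator": "synth_front_profiles",
        "seed": int(seed),
        "R0_m": float(R0),
        "true_v_m_per_s": float(v),
        "front_width_m": float(front_width),
        "sigma_rel": float(sigma_rel),
        "times_s": times.tolist(),
    }
    return frame, metadata
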