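"""End-to-end pipeline: evaporate -> pathway -> classify -> marangoni -> ribozyme.

``run_pipeline`` executes every modelling stage from a single validated
configuration and writes all outputs (CSV tables plus a JSON manifest with the
config hash, seed, package version, per-stage timings and headline numbers)
into an output directory.  Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from evapollps import __version__
from evapollps.config import PipelineConfig
from evapollps.errors import EvapoLLPSError
from evapollps.evaporation import evolve_droplet
from evapollps.hydrodynamics import (
    achievable_delta_gamma,
    bond_number,
    capillary_velocity_scale,
    marangoni_velocity_scale,
    required_delta_gamma,
)
from evapollps.phase_kinetics import classify_regime, kinetic_pathway
from evapollps.ribozyme_rd import compare_scenarios

logger = logging.getLogger("evapollps.pipeline")

__all__ = ["run_pipeline"]


class StageFailure(EvapoLLPSError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write outputs plus a manifest to ``out_dir``.

    Returns the manifest dict.  Stage failures abort the run with
    :class:`StageFailure`; outputs written so far are listed in the partial
    manifest saved alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "stages": {},
        "outputs": [],
    }

    ambient = config.ambient.build()
    geom = config.droplet.build()
    fluid = config.fluid.build()
    binodal = config.binodal.build()

    def _stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageFailure(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        logger.info("stage %s: done in %.2fs", name, dt)
        return result

    def _evaporate():
        trace = evolve_droplet(
            geom, ambient, config.pathway.delta_t_s, config.evaporation_steps
        )
        path = out / "evaporation_trace.csv"
        trace.to_frame().to_csv(path, index=False)
        manifest["outputs"].append(path.name)
        return trace

    trace = _stage("evaporate", _evaporate)
    manifest["stages"]["evaporate"]["final_contact_angle_deg"] = float(
        np.rad2deg(trace.geometries[-1].contact_angle)
    )

    def _pathway():
        path = kinetic_pathway(
            config.pathway.composition(),
            geom,
            ambient,
            binodal,
            config.binodal.tie_slope,
            delta_r_fraction=config.pathway.delta_r_fraction,
            delta_t=config.pathway.delta_t_s,
            n_steps=config.pathway.n_steps,
            solution_density=config.pathway.solution_density_kg_m3,
        )
        csv = out / "kinetic_pathway.csv"
        path.to_frame().to_csv(csv, index=False)
        manifest["outputs"].append(csv.name)
        return path

    pathway = _stage("pathway", _pathway)
    first = pathway.first_split
    if first is not None:
        manifest["stages"]["pathway"]["first_split_ratio_dex_to_peg"] = float(
            first.split.ratio_dex_to_peg
        )
        manifest["stages"]["pathway"]["final_tll"] = float(pathway.steps[-1].tll)

    def _classify():
        c0 = config.pathway.composition()
        return {
            "empirical": classify_regime(c0, mode="empirical"),
            "lever_ratio": classify_regime(
                c0,
                mode="lever_ratio",
                binodal=binodal,
                tie_slope=config.binodal.tie_slope,
                geom=geom,
                ambient=ambient,
                n_steps=max(config.pathway.n_steps, 3),
                delta_r_fraction=config.pathway.delta_r_fraction,
                delta_t=config.pathway.delta_t_s,
                solution_density=config.pathway.solution_density_kg_m3,
            ),
        }

    regimes = _stage("classify", _classify)
    manifest["stages"]["classify"].update(regimes)

    def _marangoni():
        u_cap = capillary_velocity_scale(geom, ambient, fluid)
        dgamma_req = required_delta_gamma(geom, ambient, fluid)
        # composition jump produced by the first phase split at the rim
        if first is not None:
            w_peg_jump = (
                config.pathway.composition().w_peg,
                first.split.tie_line.dex_rich.w_peg,
            )
        else:
            w_peg_jump = (config.pathway.composition().w_peg, 0.0005)
        result = {
            "bond_number": bond_number(fluid, geom),
            "capillary_velocity_m_s": u_cap,
            "required_delta_gamma_mN_m": dgamma_req * 1e3,
            "achievable_delta_gamma_mN_m": achievable_delta_gamma(fluid, *w_peg_jump)
            * 1e3,
            "marangoni_velocity_at_required_m_s": marangoni_velocity_scale(
                dgamma_req, geom, fluid
            ),
        }
        path = out / "marangoni.json"
        path.write_text(json.dumps(result, indent=2))
        manifest["outputs"].append(path.name)
        return result

    marangoni = _stage("marangoni", _marangoni)
    manifest["stages"]["marangoni"].update(
        {k: v for k, v in marangoni.items() if isinstance(v, float)}
    )

    def _ribozyme():
        params, grid = config.ribozyme.build()
        comparison = compare_scenarios(params, grid)
        for tag in ("dextran", "water"):
            curve = comparison[tag]
            csv = out / f"productivity_{tag}.csv"
            import pandas as pd

            pd.DataFrame({"t_prime": curve.t_prime, "m_p": curve.m_p}).to_csv(
                csv, index=False
            )
            manifest["outputs"].append(csv.name)
        summary = {
            "time_to_plateau_ratio": comparison["time_to_plateau_ratio"],
            "plateau_ratio": comparison["plateau_ratio"],
        }
        path = out / "ribozyme_comparison.json"
        path.write_text(json.dumps(summary, indent=2))
        manifest["outputs"].append(path.name)
        return summary

    ribozyme = _stage("ribozyme", _ribozyme)
    manifest["stages"]["ribozyme"].update(ribozyme)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
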