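"""Pipeline configuration schema (pydantic) and its physical-unit front door.

The JSON config is organized in per-stage blocks.  User-facing fields use
laboratory units (uL, degrees, %RH, wt%); the accessors convert to the SI
quantities the library works in.  Unknown keys are rejected so typos fail
loudly before any stage runs.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from evapollps.evaporation import AmbientConditions, DropletGeometry
from evapollps.hydrodynamics import FluidProperties
from evapollps.phase_kinetics import Composition, MerchukBinodal
from evapollps.ribozyme_rd import RDGrid, RDParameters

__all__ = ["PipelineConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AmbientBlock(_Block):
    vapor_diffusivity_m2_s: float = Field(2.5e-5, gt=0)
    saturated_vapor_concentration_kg_m3: float = Field(2.3e-2, gt=0)
    relative_humidity: float = Field(0.6, ge=0, le=1)

    def build(self) -> AmbientConditions:
        return AmbientConditions.from_relative_humidity(
            self.relative_humidity,
            self.vapor_diffusivity_m2_s,
            self.saturated_vapor_concentration_kg_m3,
        )


class DropletBlock(_Block):
    volume_uL: float = Field(0.5, gt=0)
    contact_angle_deg: float = Field(45.0, gt=0, lt=90)

    def build(self) -> DropletGeometry:
        return DropletGeometry.from_volume(
            self.volume_uL * 1e-9, np.deg2rad(self.contact_angle_deg)
        )


class FluidBlock(_Block):
    density_kg_m3: float = Field(1030.0, gt=0)
    viscosity_Pa_s: float = Field(0.01, gt=0)
    surface_tension_mN_m: float = Field(64.0, gt=0)
    surface_tension_ref_w_peg: float = Field(0.05, ge=0)
    surface_tension_slope_mN_m: float = Field(-70.0, lt=0)

    def build(self) -> FluidProperties:
        return FluidProperties(
            density=self.density_kg_m3,
            viscosity=self.viscosity_Pa_s,
            surface_tension_ref=self.surface_tension_mN_m * 1e-3,
            surface_tension_ref_w_peg=self.surface_tension_ref_w_peg,
            surface_tension_slope=self.surface_tension_slope_mN_m * 1e-3,
        )


class BinodalBlock(_Block):
    """Either a coexistence-table CSV path or synthetic Merchuk parameters."""

    table_csv: str | None = None
    a: float = 0.35
    b: float = -5.8
    c: float = 2.0
    d: float = -200.0
    validity_w_dex: tuple[float, float] = (0.002, 0.55)
    tie_slope: float = Field(-0.55, lt=0)

    def build(self) -> MerchukBinodal:
        if self.table_csv is not None:
            import pandas as pd

            from evapollps.phase_kinetics import fit_binodal

            table = pd.read_csv(self.table_csv)
            mask = (
                table["tie_id"].isna() | (table["tie_id"] == "")
                if "tie_id" in table
                else np.ones(len(table), dtype=bool)
            )
            pts = table.loc[mask, ["w_dex_wt_pct", "w_peg_wt_pct"]].to_numpy() / 100.0
            return fit_binodal(pts, validity=self.validity_w_dex)
        return MerchukBinodal(
            a=self.a, b=self.b, c=self.c, d=self.d, validity=self.validity_w_dex
        )


class PathwayBlock(_Block):
    c0_wt_pct: tuple[float, float] = (9.0, 4.0)  # (PEG, dextran)
    delta_r_fraction: float = Field(0.05, gt=0, lt=1)
    delta_t_s: float = Field(5.0, gt=0)
    n_steps: int = Field(2, ge=1)
    solution_density_kg_m3: float = Field(1030.0, gt=0)

    def composition(self) -> Composition:
        return Composition.from_wt_percent(*self.c0_wt_pct)


class RibozymeBlock(_Block):
    rna_diffusivity_m2_s: float = Field(1e-10, gt=0)
    kcat_per_s: float = Field(0.017, gt=0)
    K_M_mol_m3: float = Field(1e-4, gt=0)
    e_bulk_mol_m3: float = Field(1e-5, gt=0)
    s_bulk_mol_m3: float = Field(1e-4, gt=0)
    domain_radius_um: float = Field(10.0, gt=0)
    K_E: float = Field(50.0, ge=0)
    K_S: float = Field(5.0, ge=0)
    K_P: float = Field(1.0, ge=0)
    n_nodes: int = Field(200, ge=20)
    t_end_s: float = Field(10.0, gt=0)

    def build(self) -> tuple[RDParameters, RDGrid]:
        params = RDParameters(
            rna_diffusivity=self.rna_diffusivity_m2_s,
            kcat=self.kcat_per_s,
            K_M=self.K_M_mol_m3,
            e_bulk=self.e_bulk_mol_m3,
            s_bulk=self.s_bulk_mol_m3,
            domain_radius=self.domain_radius_um * 1e-6,
            K_E=self.K_E,
            K_S=self.K_S,
            K_P=self.K_P,
        )
        return params, RDGrid(n_nodes=self.n_nodes, t_end=self.t_end_s)


class PipelineConfig(_Block):
    ambient: AmbientBlock = AmbientBlock()
    droplet: DropletBlock = DropletBlock()
    fluid: FluidBlock = FluidBlock()
    binodal: BinodalBlock = BinodalBlock()
    pathway: PathwayBlock = PathwayBlock()
    ribozyme: RibozymeBlock = RibozymeBlock()
    evaporation_steps: int = Field(60, ge=1)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _sanity(self) -> "PipelineConfig":
        lo, hi = self.binodal.validity_w_dex
        if not 0 <= lo < hi:
            raise ValueError("binodal validity range must satisfy 0 <= lo < hi")
        return self

    def config_hash(self) -> str:
        """Stable hash over the semantically meaningful configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON config file."""
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))
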