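"""Run configuration: validated, preset-aware, dimensionless-internal.

A :class:`SimulationConfig` holds everything a run needs — geometry, fluid,
cell, aggregation, adhesion and drive parameters plus run controls — in
*dimensionless* units, together with the :class:`~vesselflow.units.UnitSystem`
used to convert to/from SI.  Configs are built either programmatically or
from a flat YAML document via :func:`load_config`; unknown keys are rejected
so that typos fail loudly.

Two named parameter presets mirror the two experimental settings the
simulator is validated against:

``table1``
    The microcirculation parameter set (RBC + CTC moduli, bond kinetics)
    in the default unit system.
``plate_validation``
    The deformable-capsule-on-a-plate adhesion benchmark: a spherical
    capsule of radius R = 3.75 um in Couette flow at 7000 1/s, with
    lambda = 50 nm, l_r = 375 nm, sigma_f = 0.02 E_A, sigma_d = 0.98 E_A
    and bond strength from K_SP = E_A/(eta R gamma') = 250.
"""

from __future__ import annotations

import math
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .units import ConfigurationError, UnitSystem, nondimensionalize


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Section):
    kind: Literal["couette", "tube", "bifurcation"] = "tube"
    # tube / bifurcation parent diameter, couette capsule radius R — all
    # dimensionless (characteristic lengths).
    diameter: float = 11.0
    length: float = 20.0
    couette_R: float = 1.875
    couette_box: tuple[float, float, float] = (10.0, 6.0, 6.0)
    daughter_ratio: float = 0.5
    angle: float = 1.0471975511965976  # 60 degrees between daughters
    spacing: float = 0.5
    shear_rate: float = 0.0  # couette top-wall shear rate (dimensionless)


class FluidConfig(_Section):
    number_density: float = 8.0
    particle_mass: float = 1.0
    viscosity: float = 197.0
    kBT: float = 1.0
    sound_speed: float = 0.0  # 0 -> auto from flow speed at build time
    # short-range fluid-membrane repulsion keeping fluid particles from
    # slipping between membrane vertices (membranes stay impermeable at
    # coarse mesh resolution); range covers the triangle interiors
    membrane_barrier_strength: float = 60.0
    membrane_barrier_range: float = 0.4

    @model_validator(mode="after")
    def _check(self) -> "FluidConfig":
        if self.viscosity <= 0:
            raise ConfigurationError("fluid viscosity must be > 0")
        if self.kBT < 0:
            raise ConfigurationError("fluid kBT must be >= 0 (0 disables thermal noise)")
        return self


class CellSpec(_Section):
    kind: Literal["rbc", "ctc", "capsule"] = "rbc"
    count: int = 0
    diameter: float = 3.91
    n_vertices: int = 162
    shear_modulus: float = 5794.0
    bending_modulus: float = 50.0
    dilation_modulus: float = 1.22e5
    has_receptors: bool = False

    @model_validator(mode="after")
    def _check(self) -> "CellSpec":
        if self.count < 0:
            raise ConfigurationError("cell count must be >= 0")
        if self.diameter <= 0:
            raise ConfigurationError("cell diameter must be > 0")
        return self


class AggregationConfig(_Section):
    enabled: bool = True
    # Morse surface-energy strength, zero-force distance, scaling factor,
    # and interaction cutoff (dimensionless).  Defaults follow the
    # weak-aggregation calibration of the cell-interaction literature:
    # De = 0.3 uJ/m^2, r0 = 0.49 um, beta = 3.84 um^-1.
    strength: float = 289.7
    zero_force_distance: float = 0.245
    beta: float = 7.68
    # phi(cutoff)/phi(r0) ~ 3% at 0.7; larger cutoffs buy accuracy for cost
    cutoff: float = 0.7
    clamp_negative_projection: bool = False
    # isotropic vertex-vertex excluded-volume repulsion between different
    # cells; keeps coarse membranes from interpenetrating where the
    # normal-weighted Morse term cannot
    contact_strength: float = 200.0
    contact_range: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "AggregationConfig":
        if self.strength < 0 or self.zero_force_distance <= 0 or self.beta <= 0:
            raise ConfigurationError("aggregation parameters must be positive")
        if self.cutoff <= self.zero_force_distance:
            raise ConfigurationError("aggregation cutoff must exceed zero-force distance")
        return self


class AdhesionConfig(_Section):
    enabled: bool = True
    adhesion_strength: float = 2.897e4  # E_A
    equilibrium_length: float = 0.1  # lambda
    reactive_distance: float = 0.5  # l_r
    formation_strength: float = 5.794e2  # sigma_f
    dissociation_strength: float = 7.281e2  # sigma_d
    formation_rate: float = 1184.1  # k_f0 (unstressed)
    dissociation_rate: float = 348.8  # k_d0 (unstressed)
    ligand_density: float = 12.0  # sites per dimensionless area (3 um^-2)
    single_bond_per_receptor: bool = True
    allow_multibond_ligand: bool = True
    # effective temperature of the bond kinetics; None -> fluid kBT.  A
    # coarse-grained bond stands for tens of molecular bonds, so its
    # strain-rate exponentials may carry a larger effective compliance.
    kBT: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "AdhesionConfig":
        if not (self.reactive_distance > self.equilibrium_length > 0):
            raise ConfigurationError(
                "adhesion requires l_r > lambda > 0 "
                f"(got l_r={self.reactive_distance}, lambda={self.equilibrium_length})"
            )
        for name in ("adhesion_strength", "formation_strength", "dissociation_strength",
                     "formation_rate", "dissociation_rate", "ligand_density"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"adhesion {name} must be >= 0")
        return self


class DriveConfig(_Section):
    acceleration: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region: Literal["all", "inlet"] = "all"
    inlet_length: float = 0.0


class WallConfig(_Section):
    repulsion_strength: float = 200.0
    repulsion_range: float = 0.25
    # short-range friction enhancement for fluid-wall pairs; calibrated
    # once against the analytic Poiseuille profile (no-slip correction)
    viscosity_factor: float = 3.0
    # extrapolated (antisymmetric) ghost velocities; exact for linear shear
    # profiles (Couette), off by default for curved profiles
    morris_ghosts: bool = False


class RunConfig(_Section):
    time_step: float = 1.0e-3
    n_steps: int = 1000
    seed: int = 0
    output_every: int = 100

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.time_step <= 0:
            raise ConfigurationError(f"time step must be > 0, got {self.time_step}")
        if self.n_steps < 0 or self.output_every <= 0:
            raise ConfigurationError("n_steps must be >= 0 and output_every > 0")
        return self


class SimulationConfig(_Section):
    """Fully validated, dimensionless run configuration."""

    preset: Optional[str] = None
    unit_system: UnitSystem = UnitSystem()
    geometry: GeometryConfig = GeometryConfig()
    fluid: FluidConfig = FluidConfig()
    cells: list[CellSpec] = []
    aggregation: AggregationConfig = AggregationConfig()
    adhesion: AdhesionConfig = AdhesionConfig()
    drive: DriveConfig = DriveConfig()
    wall: WallConfig = WallConfig()
    run: RunConfig = RunConfig()

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)


def _nd(u: UnitSystem, value: float, kind: str) -> float:
    return nondimensionalize(value, kind, u)


def _table1_preset(u: UnitSystem) -> dict[str, Any]:
    """Microcirculation parameter set, converted from SI at full precision."""
    sm = "surface-modulus"
    return {
        "fluid": {
            "number_density": 8.0,
            "particle_mass": 1.0,
            "viscosity": _nd(u, 1.0e-4, "viscosity"),
            "kBT": _nd(u, 4.142e-21, "temperature"),
        },
        "cells": [
            {
                "kind": "rbc",
                "diameter": _nd(u, 7.82e-6, "length"),
                "shear_modulus": _nd(u, 6.0e-6, sm),
                "bending_modulus": _nd(u, 2.07e-19, "bending-modulus"),
                "dilation_modulus": _nd(u, 1.26e-4, sm),
                "has_receptors": False,
            },
            {
                "kind": "ctc",
                "diameter": _nd(u, 9.0e-6, "length"),
                "shear_modulus": _nd(u, 1.0e-6, sm),
                "bending_modulus": _nd(u, 1.35e-19, "bending-modulus"),
                "dilation_modulus": _nd(u, 1.16e-4, sm),
                "has_receptors": True,
            },
        ],
        "adhesion": {
            "adhesion_strength": _nd(u, 3.0e-5, sm),
            "equilibrium_length": _nd(u, 0.2e-6, "length"),
            "reactive_distance": _nd(u, 1.0e-6, "length"),
            "formation_strength": _nd(u, 6.0e-7, sm),
            "dissociation_strength": _nd(u, 7.54e-7, sm),
            "formation_rate": _nd(u, 1.205e6, "rate"),
            "dissociation_rate": _nd(u, 3.55e5, "rate"),
            "ligand_density": 3.0e12 * u.l_ref**2,  # 3 sites per um^2
        },
    }


def _plate_validation_preset(u: UnitSystem) -> dict[str, Any]:
    """Capsule-on-a-plate adhesion benchmark (physical values converted)."""
    sm = "surface-modulus"
    R = 3.75e-6
    eta = 1.0e-3
    gamma = 7000.0
    E_A = 250.0 * eta * R * gamma  # K_SP = 250
    return {
        "geometry": {
            "kind": "couette",
            "couette_R": _nd(u, R, "length"),
            "shear_rate": _nd(u, gamma, "shear-rate"),
        },
        "fluid": {
            "number_density": 8.0,
            "particle_mass": 1.0,
            "viscosity": _nd(u, eta, "viscosity"),
            "kBT": 1.0,
        },
        "cells": [
            {
                "kind": "capsule",
                "count": 1,
                "diameter": _nd(u, 2 * R, "length"),
                # Ca = 0.005 by default; the Ca = 0.015 variant divides by 3.
                "shear_modulus": _nd(u, eta * gamma * R / 0.005, sm),
                "bending_modulus": _nd(u, 0.02 * R**2 * (eta * gamma * R / 0.005), "bending-modulus"),
                "dilation_modulus": _nd(u, 100.0 * (eta * gamma * R / 0.005), sm),
                "has_receptors": True,
            }
        ],
        "aggregation": {"enabled": False},
        "adhesion": {
            "adhesion_strength": _nd(u, E_A, sm),
            "equilibrium_length": _nd(u, 50.0e-9, "length"),
            "reactive_distance": _nd(u, 375.0e-9, "length"),
            "formation_strength": _nd(u, 0.02 * E_A, sm),
            "dissociation_strength": _nd(u, 0.98 * E_A, sm),
            "formation_rate": _nd(u, 10.0 * gamma, "rate"),  # K_f = 10
            "dissociation_rate": _nd(u, 1.0 * gamma, "rate"),  # K_d = 1.0 (or 0.01)
        },
    }


PRESETS = {
    "table1": _table1_preset,
    "plate_validation": _plate_validation_preset,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def make_config(data: Optional[dict] = None, **kwargs: Any) -> SimulationConfig:
    """Build a validated config from a plain dict, expanding any preset."""
    data = _deep_merge(data or {}, kwargs)
    preset_name = data.get("preset")
    if preset_name is not None:
        try:
            preset_fn = PRESETS[preset_name]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
            ) from None
        unit_kwargs = data.get("unit_system", {})
        u = UnitSystem(**unit_kwargs) if isinstance(unit_kwargs, dict) else unit_kwargs
        data = _deep_merge(preset_fn(u), data)
    try:
        return SimulationConfig(**data)
    except ConfigurationError:
        raise
    except Exception as exc:  # pydantic ValidationError -> uniform error type
        raise ConfigurationError(str(exc)) from exc


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    The document is a nested mapping mirroring :class:`SimulationConfig`;
    a top-level ``preset`` key expands one of the named presets before the
    file's own keys are applied on top.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return make_config(raw)
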