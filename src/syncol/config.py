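"""Run configuration: nested parameter blocks with nominal defaults.

An empty configuration file reproduces the nominal parameter set of the
study (reactor geometry, Table-style kinetic and physical constants,
60/40 CO/H2 feed, saturated initial liquid, 1000 h startup horizon).
Every numeric field carries one fixed documented unit; no unit algebra
is performed.  The gas volume fraction is computed from the holdup
correlation and is deliberately not a configuration field.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import kinetics as kin
from .simulator import RecycleSpec, SimulationSettings

__all__ = ["RunConfig", "read_config", "write_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelBlock(_Block):
    """Metabolic model source; None selects the bundled toy network."""

    source: str | None = None
    format: str | None = None
    roles: dict[str, str] = Field(default_factory=dict)


class KineticsBlock(_Block):
    """Uptake kinetics (v_max mmol/gDW/h, K_m mmol/L, K_I g/L)."""

    v_max: dict[str, float] = Field(
        default_factory=lambda: {"co": 35.0, "h2": 70.0, "co2": 35.0}
    )
    k_m: dict[str, float] = Field(
        default_factory=lambda: {"co": 0.02, "h2": 0.02, "co2": 0.02}
    )
    k_i_product: float = 10.0
    co_inhibition: bool = False
    k_i_co_on_co: float = 1.0e6
    k_i_co_on_h2: float = 1.0e6


class GasBlock(_Block):
    """Henry constants (mol/L/atm), k_m (1/h), T (K), P_top (Pa), holdup fit."""

    henry: dict[str, float] = Field(
        default_factory=lambda: {"co": 8.0e-4, "h2": 6.6e-4, "co2": 2.5e-2}
    )
    k_m: dict[str, float] = Field(
        default_factory=lambda: {"co": 80.0, "h2": 200.0, "co2": 80.0}
    )
    temperature: float = 310.15
    pressure_top: float = 1.013e5
    rho_liquid: float = 1000.0
    gravity: float = 9.81
    eps_g_max: float = 0.53
    k_g: float = 540.0
    partial_pressure_mode: str = "concentration"


class GeometryBlock(_Block):
    """Column length (m), area (m^2), u_G and u_L (m/h), D_A (m^2/h)."""

    length: float = 25.0
    area: float = 5.0
    u_gas: float = 75.0
    u_liquid: float = 0.25
    dispersion: float = 0.25


class FeedBlock(_Block):
    """Feed gas mole fractions (must sum to one)."""

    x_co: float = 0.6
    x_h2: float = 0.4
    x_co2: float = 0.0


class InitialBlock(_Block):
    """Initial biomass and product titers; gases start saturated."""

    biomass: float = 0.1
    ethanol: float = 0.0
    acetate: float = 0.0


class SimulationBlock(_Block):
    final_time: float = 1000.0
    n_nodes: int = 100
    rtol: float = 1.0e-3
    atol: float = 1.0e-6
    steady_threshold: float = 1.0e-2
    n_snapshots: int = 11
    scheme: str = "third-order-upwind"
    seed: int | None = None
    stop_at_steady: bool = True


class RecycleBlock(_Block):
    alpha: float = 0.0
    fixed_point_tol: float = 1.0e-4
    max_passes: int = 50


class RunConfig(_Block):
    """Complete configuration of one column simulation."""

    model: ModelBlock = Field(default_factory=ModelBlock)
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    gas: GasBlock = Field(default_factory=GasBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    feed: FeedBlock = Field(default_factory=FeedBlock)
    initial: InitialBlock = Field(default_factory=InitialBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    recycle: RecycleBlock | None = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        s = self.feed.x_co + self.feed.x_h2 + self.feed.x_co2
        if abs(s - 1.0) > 1e-12:
            raise ValueError(
                f"feed mole fractions sum to {s!r}, expected 1 "
                "(x_co + x_h2 + x_co2 = 1)"
            )
        return self

    # -- conversions to runtime objects --------------------------------
    def to_uptake_kinetics(self) -> kin.UptakeKinetics:
        k = self.kinetics
        return kin.UptakeKinetics(
            v_max=dict(k.v_max),
            k_m=dict(k.k_m),
            k_i_product=k.k_i_product,
            k_i_co_on_co=k.k_i_co_on_co,
            k_i_co_on_h2=k.k_i_co_on_h2,
            co_inhibition=k.co_inhibition,
        )

    def to_gas_params(self) -> kin.GasPhysicalParams:
        g = self.gas
        return kin.GasPhysicalParams(
            henry=dict(g.henry),
            k_m=dict(g.k_m),
            temperature=g.temperature,
            pressure_top=g.pressure_top,
            rho_liquid=g.rho_liquid,
            gravity=g.gravity,
            eps_g_max=g.eps_g_max,
            k_g=g.k_g,
            partial_pressure_mode=g.partial_pressure_mode,
        )

    def to_geometry(self) -> kin.ColumnGeometry:
        g = self.geometry
        return kin.ColumnGeometry(
            length=g.length,
            area=g.area,
            u_gas=g.u_gas,
            u_liquid=g.u_liquid,
            dispersion=g.dispersion,
        )

    def to_settings(self) -> SimulationSettings:
        s = self.simulation
        return SimulationSettings(
            final_time=s.final_time,
            n_nodes=s.n_nodes,
            rtol=s.rtol,
            atol=s.atol,
            steady_threshold=s.steady_threshold,
            n_snapshots=s.n_snapshots,
            scheme=s.scheme,
            seed=s.seed,
            stop_at_steady=s.stop_at_steady,
        )

    def to_recycle(self) -> RecycleSpec | None:
        if self.recycle is None:
            return None
        return RecycleSpec(
            alpha=self.recycle.alpha,
            fixed_point_tol=self.recycle.fixed_point_tol,
            max_passes=self.recycle.max_passes,
        )

    def feed_tuple(self) -> tuple[float, float, float]:
        return (self.feed.x_co, self.feed.x_h2, self.feed.x_co2)

    # -- overrides ------------------------------------------------------
    def with_override(self, path: str, value) -> "RunConfig":
        """Copy with one dotted-path field replaced.

        Overriding a feed mole fraction rebalances the complementary
        fraction (x_h2 for x_co and vice versa) so the sum stays at one,
        matching how the feed-composition sweeps are defined.
        """
        data = self.model_dump()
        parts = path.split(".")
        target = data
        for p in parts[:-1]:
            if p not in target or not isinstance(target[p], dict):
                raise KeyError(f"unknown parameter path {path!r}")
            target = target[p]
        if parts[-1] not in target:
            raise KeyError(f"unknown parameter path {path!r}")
        target[parts[-1]] = value
        if parts[0] == "feed":
            feed = data["feed"]
            if parts[-1] == "x_co":
                feed["x_h2"] = 1.0 - feed["x_co"] - feed["x_co2"]
            elif parts[-1] == "x_h2":
                feed["x_co"] = 1.0 - feed["x_h2"] - feed["x_co2"]
            elif parts[-1] == "x_co2":
                feed["x_h2"] = 1.0 - feed["x_co"] - feed["x_co2"]
        return RunConfig.model_validate(data)

    def to_dict(self) -> dict:
        return self.model_dump()


def read_config(path: str | Path | None) -> RunConfig:
    """Read a YAML or JSON configuration; missing fields take defaults.

    An empty file (or None) yields the full nominal configuration.
    Unknown keys and cross-field violations raise :class:`ConfigError`
    with an itemized message.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a configuration; the write -> read round trip is lossless."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
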