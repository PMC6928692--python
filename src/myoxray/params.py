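"""Typed configuration for the half-sarcomere model.

All lengths carry their unit in the field name or docstring; the internal
working unit is the nanometre (sarcomere lengths are entered in micrometres,
as customary) and forces are in piconewtons.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "GeometryParams",
    "ElasticParams",
    "RateParams",
    "SimulationConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class GeometryParams:
    """Half-sarcomere lattice geometry of vertebrate striated muscle.

    Defaults describe bullfrog sartorius at a sarcomere length of 2.3 um:
    ~1 um thin filaments of 364 monomers at 2.73 nm axial rise, 1.58 um thick
    filaments carrying 50 crowns of 3 heads at 14.3 nm, and a hexagonal
    filament lattice with d10 = 36.5 nm (37 nm at the 2.15 um slack length,
    used only for areal filament densities).
    """

    sarcomere_length_um: float = 2.3
    thin_length_um: float = 1.0
    n_monomers: int = 364
    monomer_spacing_s0_nm: float = 2.73
    strand_half_period_nm: float = 35.5
    thick_length_um: float = 1.58
    n_crowns: int = 50
    crown_spacing_nm: float = 14.3
    heads_per_crown: int = 3
    d10_sim_nm: float = 36.5
    d10_slack_nm: float = 37.0
    myofibril_occupancy: float = 0.8
    n_thick: int = 500
    n_thin: int = 1000
    # Axial distance from the M-band plane to the crown nearest it.  The
    # default places the distal crown at the thin-filament tip at SL 2.3 um,
    # which realises the maximum thick-thin overlap of ~0.7 um.
    bare_zone_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_thick < 1:
            raise ValueError("n_thick must be >= 1")
        if self.n_thin != 2 * self.n_thick:
            object.__setattr__(self, "n_thin", 2 * self.n_thick)
        if self.bare_zone_nm is None:
            # 2.3 um reference SL: half sarcomere 1150 nm, thin tip at
            # n_monomers * s0 = 993.7 nm.
            bare = 1150.0 - self.n_monomers * self.monomer_spacing_s0_nm
            object.__setattr__(self, "bare_zone_nm", bare)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def half_sarcomere_nm(self) -> float:
        return self.sarcomere_length_um * 1000.0 / 2.0

    @property
    def thin_length_nm(self) -> float:
        """Thin filament axial extent (monomer count x axial rise)."""
        return self.n_monomers * self.monomer_spacing_s0_nm

    @property
    def heads_per_half_thick(self) -> int:
        return self.n_crowns * self.heads_per_crown

    @property
    def crown_span_nm(self) -> float:
        return (self.n_crowns - 1) * self.crown_spacing_nm

    def crown_rest_positions_nm(self):
        """Axial rest positions of the 50 crowns, Z-disc frame (z=0 at Z-disc,
        increasing toward the M-band); index 0 is the crown nearest the Z-disc."""
        import numpy as np

        distal = self.half_sarcomere_nm - self.bare_zone_nm
        return distal - (self.n_crowns - 1 - np.arange(self.n_crowns)) * self.crown_spacing_nm

    def validate(self) -> None:
        if not (0 < self.myofibril_occupancy <= 1):
            raise ValueError("myofibril_occupancy must be in (0, 1]")
        for name in ("monomer_spacing_s0_nm", "crown_spacing_nm", "thin_length_um",
                     "d10_sim_nm", "d10_slack_nm", "sarcomere_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.thin_length_nm - self.thin_length_um * 1000.0) > 0.01 * self.thin_length_um * 1000.0:
            raise ValueError(
                "n_monomers x monomer spacing must reproduce thin_length within 1%"
            )


@dataclass(frozen=True)
class ElasticParams:
    """Filament moduli (stiffness x length) and crossbridge spring constant.

    A modulus K means a segment of length L has stiffness K/L; Ka = 0.65e5 pN
    is equivalent to 65 pN/nm for a 1 um actin filament.
    """

    Ka_pN: float = 0.65e5
    Km_pN: float = 1.32e5
    kappa_xb_pN_per_nm: float = 1.3
    titin_stiffness_pN_per_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.Ka_pN <= 0 or self.Km_pN <= 0 or self.kappa_xb_pN_per_nm <= 0:
            raise ValueError("filament moduli and crossbridge stiffness must be positive")
        if self.titin_stiffness_pN_per_nm < 0:
            raise ValueError("titin stiffness must be >= 0")


@dataclass(frozen=True)
class RateParams:
    """Three-state crossbridge cycle parameters (detached = 1, weakly
    attached / pre-stroke = 2, post-stroke = 3).

    Energies are in units of kBT; kBT itself is 3.96 pN nm (287 K).
    ``k_bind_per_s`` is the zero-strain actin attachment rate and is the one
    knob titrated against tension.
    """

    dG_bind_kBT: float = -3.0
    dG_stroke_kBT: float = -15.0
    k_bind_per_s: float = 134.0
    k_adp0_per_s: float = 70.0
    stroke_d_nm: float = 10.5
    delta2_nm: float = 1.0
    k13_per_s: float = 0.0
    cap_k23_per_s: float = 1000.0
    cap_k32_per_s: float = 100.0
    cap_k31_per_s: float = 1.0e4
    kBT_pN_nm: float = 3.96
    dt_s: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.kBT_pN_nm <= 0 or self.dt_s <= 0:
            raise ValueError("kBT and dt must be positive")
        for name in ("k_bind_per_s", "k_adp0_per_s", "k13_per_s",
                     "cap_k23_per_s", "cap_k32_per_s", "cap_k31_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def K_bind(self) -> float:
        """Zero-strain binding equilibrium constant, exp(-dG_bind) ~= 20."""
        return math.exp(-self.dG_bind_kBT)

    def max_rate_per_s(self) -> float:
        return max(self.cap_k23_per_s, self.cap_k31_per_s, self.cap_k32_per_s,
                   self.k_bind_per_s, self.k_adp0_per_s)


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of everything an isometric run needs."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    rates: RateParams = field(default_factory=RateParams)
    binding_reach_nm: float = 8.0
    solve_tol_pN: float = 1.0e-6
    record_every_s: float = 1.0e-3
    snapshot_every_s: float = 0.02
    snapshot_after_s: float = 0.2

    def replace(self, **kw: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        geo = GeometryParams(**d.pop("geometry", {}))
        ela = ElasticParams(**d.pop("elastic", {}))
        rat = RateParams(**d.pop("rates", {}))
        return cls(geometry=geo, elastic=ela, rates=rat, **d)


def load_config(path: str | Path, overrides: dict | None = None) -> SimulationConfig:
    """Read a flat or nested YAML config file.

    Flat keys mirror the dataclass field names (units in the key names);
    nested ``geometry:/elastic:/rates:`` sections are also accepted.
    ``overrides`` is a flat {field: value} mapping applied last.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    nested: dict[str, dict] = {"geometry": {}, "elastic": {}, "rates": {}}
    top: dict[str, Any] = {}
    sections = {
        "geometry": {f.name for f in dataclasses.fields(GeometryParams)},
        "elastic": {f.name for f in dataclasses.fields(ElasticParams)},
        "rates": {f.name for f in dataclasses.fields(RateParams)},
    }
    top_fields = {f.name for f in dataclasses.fields(SimulationConfig)}

    def place(key: str, value: Any) -> None:
        for sec, names in sections.items():
            if key in names:
                nested[sec][key] = value
                return
        if key in top_fields:
            top[key] = value
        else:
            raise KeyError(f"unknown config key: {key!r}")

    for key, value in raw.items():
        if key in ("geometry", "elastic", "rates") and isinstance(value, dict):
            for k, v in value.items():
                place(k, v)
        else:
            place(key, value)
    if overrides:
        for k, v in overrides.items():
            place(k, v)
    return SimulationConfig(
        geometry=GeometryParams(**nested["geometry"]),
        elastic=ElasticParams(**nested["elastic"]),
        rates=RateParams(**nested["rates"]),
        **top,
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
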