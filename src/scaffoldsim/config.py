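"""Run configuration: flat YAML schema, validation, fixtures.

Configs are flat key-value YAML files in the units the tissue-engineering
literature prints (micrometres, mm/s, g/cm^3, hours); they are converted
to SI exactly once, at load time:

    1 mm/s = 1e-3 m/s        1 g/cm^3 = 1000 kg/m^3 = 1 x 1e-3 g/cm^3
    1 cm^2/s = 1e-4 m^2/s    1 um = 1e-6 m            per kg/m^3

Unknown keys are rejected, a saved config reloads to an identical object,
and every artifact written by the package embeds the config hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .culture import OperatingConditions
from .geometry import UnitDesign
from .kinetics import KineticParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "make_fixtures", "FIXTURE_KINDS"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


#: flat config keys -> (section, default in file units)
_SCHEMA = {
    # design
    "r_um": 100.0,
    "delta_y_um": 0.0,
    "delta_z_um": 0.0,
    "cultured_surfaces": ["bottom"],
    # operating conditions
    "inlet_velocity_mm_s": 3.0,
    "glin_g_cm3": 4.5e-3,
    "initial_cell_density_cm3": 5e7,
    "duration_h": 120.0,
    "dt_h": 1.0,
    # solver
    "resolution": 32,
    "gate_mode": "remove",
    "flow_update_interval": 1,
    "occlusion": "static",
    # kinetics (defaults = the literature parameter set)
    "Vm_kg_m3_s": 3.9e-5,
    "Km_kg_m3": 6.3e-3,
    "Kg0_per_s": 5.8e-6,
    "alpha": 0.8761,
    "beta_per_Pa": 104.5,
    "Keq": 0.1,
    "Dgf_cm2_s": 1.0e-5,
    "Dgc_cm2_s": 1.0e-6,
    "Dlf_cm2_s": 1.4e-5,
    "rho_cell_g_cm3": 0.182,
    "dc_um": 13.0,
    "Kc": 2.25 / 182.0,
    "rd_per_s": 0.0,
    "Dc_cm2_s": 0.0,
    "ph_threshold": 6.8,
    # bookkeeping
    "seed": 0,
    "out_dir": "results",
    "schema_version": SCHEMA_VERSION,
}


@dataclass
class RunConfig:
    """Validated, SI-converted run configuration."""

    design: UnitDesign
    conditions: OperatingConditions
    kinetics: KineticParams
    resolution: int = 32
    gate_mode: str = "remove"
    flow_update_interval: int = 1
    occlusion: str = "static"
    seed: int = 0
    out_dir: str = "results"
    raw: dict = field(default_factory=dict)

    def hash(self) -> str:
        """Stable digest of the file-unit key-value content."""
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _from_raw(raw: dict) -> RunConfig:
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_SCHEMA)
    cfg.update(raw)
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg['schema_version']}")
    try:
        design = UnitDesign(
            r=float(cfg["r_um"]), delta_y=float(cfg["delta_y_um"]),
            delta_z=float(cfg["delta_z_um"]),
            cultured_surfaces=tuple(cfg["cultured_surfaces"]))
        conditions = OperatingConditions(
            inlet_velocity=float(cfg["inlet_velocity_mm_s"]) * 1e-3,
            glin=float(cfg["glin_g_cm3"]) * 1000.0,
            initial_cell_density=float(cfg["initial_cell_density_cm3"]),
            duration=float(cfg["duration_h"]) * 3600.0,
            dt=float(cfg["dt_h"]) * 3600.0)
        kin = KineticParams(
            Vm=float(cfg["Vm_kg_m3_s"]), Km=float(cfg["Km_kg_m3"]),
            Kg0=float(cfg["Kg0_per_s"]), alpha_c=float(cfg["alpha"]),
            beta_c=float(cfg["beta_per_Pa"]), Keq=float(cfg["Keq"]),
            Dgf=float(cfg["Dgf_cm2_s"]) * 1e-4,
            Dgc=float(cfg["Dgc_cm2_s"]) * 1e-4,
            Dlf=float(cfg["Dlf_cm2_s"]) * 1e-4,
            rho_cell=float(cfg["rho_cell_g_cm3"]) * 1000.0,
            dc=float(cfg["dc_um"]) * 1e-6, Kc=float(cfg["Kc"]),
            rd=float(cfg["rd_per_s"]), Dc=float(cfg["Dc_cm2_s"]) * 1e-4,
            ph_threshold=float(cfg["ph_threshold"]))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if int(cfg["resolution"]) < 8:
        raise ConfigError("resolution must be at least 8")
    if cfg["gate_mode"] not in ("remove", "freeze"):
        raise ConfigError("gate_mode must be 'remove' or 'freeze'")
    if cfg["occlusion"] not in ("static", "error"):
        raise ConfigError("occlusion must be 'static' or 'error'")
    return RunConfig(design=design, conditions=conditions, kinetics=kin,
                     resolution=int(cfg["resolution"]),
                     gate_mode=str(cfg["gate_mode"]),
                     flow_update_interval=int(cfg["flow_update_interval"]),
                     occlusion=str(cfg["occlusion"]),
                     seed=int(cfg["seed"]), out_dir=str(cfg["out_dir"]),
                     raw={k: cfg[k] for k in _SCHEMA})


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML run configuration.

    Missing keys take the documented defaults; unknown keys are an error
    (typos must not silently change a run).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return _from_raw(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write the full (defaults-applied) config; load(save(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)


FIXTURE_KINDS = ("reference_design", "improved_design_1",
                 "improved_design_2", "poiseuille_duct", "campaign_smoke")


def make_fixtures(kind: str, out_dir) -> list[Path]:
    """Write ready-to-run configuration files.

    * ``reference_design`` — all four fibers inscribed, D1 = D2 = 200 um
      (displacements 100/100, the inverse sagitta of D = 2r).
    * ``improved_design_1`` — delta_y = 7 um, delta_z = 90 um: the best
      single-cultured-fiber design of the first screening campaign.
    * ``improved_design_2`` — delta_y = 17 um, delta_z = 40 um: the best
      all-fibers-cultured design of the second campaign.
    * ``poiseuille_duct`` — empty unit (flat walls) for analytic flow
      validation.
    * ``campaign_smoke`` — a seeded 5-candidate campaign spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recipes = {
        "reference_design": {"delta_y_um": 100.0, "delta_z_um": 100.0},
        "improved_design_1": {"delta_y_um": 7.0, "delta_z_um": 90.0},
        "improved_design_2": {"delta_y_um": 17.0, "delta_z_um": 40.0,
                              "cultured_surfaces": ["top", "bottom",
                                                    "front", "back"]},
        "poiseuille_duct": {"delta_y_um": 0.0, "delta_z_um": 0.0},
        "campaign_smoke": {"delta_y_um": 0.0, "delta_z_um": 0.0,
                           "duration_h": 4.0, "resolution": 12,
                           "seed": 42},
    }
    if kind not in recipes:
        raise ConfigError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    raw = recipes[kind]
    cfg = _from_raw(raw)
    path = out_dir / f"{kind}.yaml"
    save_config(cfg, path)
    written = [path]
    if kind == "campaign_smoke":
        spec = {"n_candidates": 5, "seed": 42, "range_um": [0.0, 100.0]}
        spath = out_dir / "campaign_smoke_spec.yaml"
        with open(spath, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=True)
        written.append(spath)
    return written
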