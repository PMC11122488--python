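"""Run configuration: schema, defaults, validation, serialization.

A single structured text file (YAML; JSON is a YAML subset and is equally
accepted) configures a run.  Units are fixed across the schema — mm, N,
MPa, day, and seconds for waveforms — so any unit conversion happens
exactly once, at load time.  Unknown keys are rejected; every unset field
resolves to a documented default and is echoed into the run log together
with the gap-filling defaults actually used.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .degradation import KineticParams
from .loading import BalloonProgram, VesselSpec, Waveform
from .material import MaterialLaw
from .mechanics import SolverParams

__all__ = ["RunConfig", "load_config", "save_config", "write_run_log"]

# defaults that fill gaps the source data does not pin down; echoed in
# every run log so no run silently depends on them
GAP_FILLING_DEFAULTS = (
    "kinetics.stress_sensitivity",
    "kinetics.source_coeff",
    "kinetics.release_coeff",
    "kinetics.alpha_m_inf",
    "kinetics.tau_sw",
    "balloon.peak_pressure",
    "design.crowns_per_ring",
    "design.ring_amplitude",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    lambda0: float = Field(0.003, ge=0)
    stress_sensitivity: float = Field(0.02, ge=0)
    k: float = Field(0.12, ge=0)
    beta_thre: float = Field(0.01, ge=0)
    phi0: float = Field(1.2e-3, ge=0)  # mm^2/day
    theta: float = Field(9.43, ge=0)
    rho_dry: float = Field(1.2, gt=0)
    rho_water: float = Field(1.0, gt=0)
    source_coeff: float = Field(1.0, ge=0)
    release_coeff: float = Field(0.2, ge=0)
    alpha_m_inf: float = Field(0.1, ge=0)
    tau_sw: float = Field(7.0, ge=0)
    dt: float = Field(1.0, gt=0)
    rate_form: str = "additive"

    def build(self, seed: int) -> KineticParams:
        return KineticParams(seed=seed, **self.model_dump())


class MaterialConfig(_Strict):
    E_s0: float = Field(3000.0, gt=0)
    E_water: float = Field(10.0, gt=0)
    sigma_y0: float = Field(50.0, gt=0)
    nu: float = Field(0.3, ge=0, lt=0.5)
    phi: float = Field(1.225, ge=0)
    eta: float = Field(0.99, gt=0, le=1)
    modulus_form: str = "saturating"

    def build(self) -> MaterialLaw:
        return MaterialLaw(**self.model_dump())


class VesselConfig(_Strict):
    inner_diameter: float = Field(3.0, gt=0)
    thickness: float = Field(0.4, gt=0)
    length: float = Field(6.0, gt=0)
    C10: float = Field(1.023, gt=0)
    C01: float = Field(0.710, gt=0)

    def build(self) -> VesselSpec:
        return VesselSpec(**self.model_dump())


class WaveformConfig(_Strict):
    components: list[tuple[float, float, float]] = [
        (3.5, 0.1543, 0.1373),
        (0.9784, 0.4168, 0.07873),
        (13.49, 0.4487, 1.006),
    ]
    period: float = Field(0.8, gt=0)

    def build(self) -> Waveform:
        return Waveform(components=tuple(tuple(c) for c in self.components),
                        period=self.period)


class BalloonConfig(_Strict):
    ramp_up: float = Field(0.1, ge=0)
    hold: float = Field(0.1, ge=0)
    ramp_down: float = Field(0.1, ge=0)
    peak_pressure: float = Field(0.45, ge=0)

    def build(self) -> BalloonProgram:
        return BalloonProgram(**self.model_dump())


class DesignConfig(_Strict):
    name: str = "DESolve"
    crowns_per_ring: int | None = None
    ring_amplitude: float | None = None
    segment_rings: int | None = 3


class SolverConfig(_Strict):
    tol_rel: float = Field(1e-8, gt=0)
    tol_abs: float = Field(1e-9, gt=0)
    max_iter: int = Field(100, gt=0)
    contact_stiffness: float = Field(1.0e4, gt=0)

    def build(self) -> SolverParams:
        return SolverParams(**self.model_dump())


class RunConfig(_Strict):
    """Top-level run configuration with all defaults resolved."""

    design: DesignConfig = DesignConfig()
    lattice_path: str | None = None  # overrides design if given
    kinetics: KineticsConfig = KineticsConfig()
    material: MaterialConfig = MaterialConfig()
    vessel: VesselConfig = VesselConfig()
    waveform: WaveformConfig = WaveformConfig()
    balloon: BalloonConfig = BalloonConfig()
    solver: SolverConfig = SolverConfig()
    n_days: int = Field(180, ge=0)
    seed: int = Field(0, ge=0)
    output_dir: str = "."

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v >= 2**31:
            raise ValueError("seed must fit in 31 bits")
        return v


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing file fields default."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def write_run_log(cfg: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """Provenance sidecar: resolved config, seed, version, gap defaults."""
    from . import __version__

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "resolved_config": cfg.model_dump(),
        "gap_filling_defaults": list(GAP_FILLING_DEFAULTS),
    }
    if extra:
        log.update(extra)
    Path(path).write_text(json.dumps(log, indent=2, default=str))
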