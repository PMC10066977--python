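"""Configuration: physical constants, sampling ranges, solver and ML settings.

Every quantity that the lung model or blood-chemistry layer treats as a
constant is collected here so a run is fully reproducible from its config.
All blocks round-trip through YAML via :func:`load_config` /
:func:`save_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class PhysConstants:
    """Physical and physiological constants (37 degC blood assumed throughout).

    hufner          mL O2 bound per g of fully saturated hemoglobin
    o2_solubility   physically dissolved O2, mL/dL/mmHg
    co2_solubility  dissolved CO2, mmol/L/mmHg (Henderson-Hasselbalch)
    n2_solubility   physically dissolved N2 in blood, mL/dL/mmHg
    p50_reference   standard P50 of the reference dissociation curve, mmHg
    bohr_ph         d log10(P50) / d pH (Bohr shift)
    be_p50          d log10(P50) / d BE (residual non-pH shift)
    pk_bicarb       apparent pK of the bicarbonate buffer system
    k_gas           0.863: VA(L/min BTPS) * P(mmHg) -> mL/min STPD
    """

    hufner: float = 1.34
    o2_solubility: float = 0.003
    co2_solubility: float = 0.0307
    n2_solubility: float = 0.0015
    barometric: float = 760.0
    water_vapor: float = 47.0
    temperature: float = 37.0
    p50_reference: float = 26.86
    bohr_ph: float = -0.48
    be_p50: float = 0.0013
    pk_bicarb: float = 6.09072
    k_gas: float = 0.863

    @property
    def dry_pressure(self) -> float:
        """Total pressure available to alveolar gas (barometric - water vapor)."""
        return self.barometric - self.water_vapor


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the forward model and its inner solvers."""

    n_compartments: int = 20
    grid_span: float = 3.5          # V/Q grid covers mean_vq * exp(+-span*log_sd)
    venous_damping: float = 0.0     # relaxation on the mixed-venous update
    venous_tol: float = 1e-6        # mL/dL change for outer convergence
    max_outer_iter: int = 200
    newton_tol: float = 1e-11       # scaled compartment flux residual
    max_newton_iter: int = 60
    content_tol: float = 1e-10      # mL/dL, blood-state-from-contents solve
    titration_tol: float = 0.002    # SaO2 units
    max_titration_iter: int = 14


@dataclass(frozen=True)
class InputRanges:
    """Sampling envelope for the nine model inputs (low, high).

    Shunt is a fraction of pulmonary blood flow, log_sd is in natural-log
    units, mean_vq is the median (geometric mean) of the perfusion-weighted
    V/Q distribution.  VCO2 mL/min STPD, Hb g/dL, P50st mmHg, BE mEq/L,
    CO L/min.
    """

    shunt: tuple[float, float] = (0.073, 0.365)
    log_sd: tuple[float, float] = (0.36, 1.83)
    mean_vq: tuple[float, float] = (0.21, 1.25)
    vco2: tuple[float, float] = (185.0, 223.0)
    r: tuple[float, float] = (0.57, 1.05)
    hb: tuple[float, float] = (6.0, 17.3)
    p50st: tuple[float, float] = (20.8, 31.2)
    be: tuple[float, float] = (-6.5, 4.9)
    co: tuple[float, float] = (4.32, 6.28)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def validate(self) -> None:
        for name, (lo, hi) in self.as_dict().items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must satisfy low < high, got {(lo, hi)}")


@dataclass(frozen=True)
class OutputEnvelope:
    """Plausibility screen on the generated bedside observables.

    Scenarios whose steady state falls outside these windows are rejected
    and resampled: they represent non-viable physiology (e.g. pH below 7)
    that bedside monitoring of a living patient would never produce.  The
    defaults delimit the observable envelope of the simulated study
    conditions; set a bound to +-inf to disable it.
    """

    ph: tuple[float, float] = (7.02, 7.56)
    pao2: tuple[float, float] = (41.8, 127.7)
    paco2: tuple[float, float] = (23.8, 111.6)
    mean_paco2: tuple[float, float] = (14.2, 77.1)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training settings of the shunt-regressing MLP."""

    n_features: int = 10
    hidden_layers: int = 6
    units_per_layer: int = 128
    output_units: int = 1
    activation: str = "relu"
    epochs: int = 500
    batch_size: int = 200
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1   # monitored only, never used for fitting
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full simulate/train/evaluate run."""

    ranges: InputRanges = field(default_factory=InputRanges)
    constants: PhysConstants = field(default_factory=PhysConstants)
    solver: SolverSettings = field(default_factory=SolverSettings)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    n_scenarios: int = 15236
    n_test: int = 500
    sat_band: tuple[float, float] = (0.87, 0.98)
    envelope: OutputEnvelope = field(default_factory=OutputEnvelope)
    seed: int = 0

    def digest(self) -> str:
        """Short stable hash of the config, embedded in artifacts."""
        import hashlib
        import json

        payload = json.dumps(to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def to_dict(cfg: Any) -> Any:
    """Recursively convert nested config dataclasses to plain containers."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return list(cfg)
    return cfg


_SUBCONFIGS = {
    "ranges": InputRanges,
    "constants": PhysConstants,
    "solver": SolverSettings,
    "mlp": MLPConfig,
    "envelope": OutputEnvelope,
}


def _build(cls: type, data: dict[str, Any]) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in _SUBCONFIGS.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key) or {})
    top = _build(RunConfig, data)
    return dataclasses.replace(top, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; missing keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = config_from_dict(data)
    cfg.ranges.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)


DEFAULT_CONSTANTS = PhysConstants()
DEFAULT_SOLVER = SolverSettings()
DEFAULT_RANGES = InputRanges()
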