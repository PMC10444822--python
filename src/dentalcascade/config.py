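"""Simulation configuration files: YAML schema, validation, shipped presets.

A simulation config has one block per cascade (``premolar``, ``molar``),
each fully specifying an :class:`~dentalcascade.rd_simulator.RDParameters`:
diffusivities, a kinetics block (registry name + constants), a growth
schedule as piecewise-linear (Carnegie stage, added length per stage) pairs,
an optional gradient spec, grid and detection settings, and a seed.  Stages
are mapped to simulation time through ``stage0`` and ``time_per_stage``.

Four presets ship with the package, one per morphogroup:
``regular_jaw``, ``long_jaw``, ``intermediate_jaw``, ``short_jaw_artibeus``.
Their constants were calibrated so that each reproduces its morphogroup's
premolar/molar insertion-count phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .kinetics import get_kinetics
from .rd_simulator import (
    Detection, GradientSpec, Grid, GrowthSchedule, RDParameters,
)

SHIPPED = ("regular_jaw", "long_jaw", "intermediate_jaw", "short_jaw_artibeus")


def shipped_config_names() -> tuple[str, ...]:
    return SHIPPED


@dataclass(frozen=True)
class SimulationConfig:
    """One resolved morphogroup simulation: paired cascade parameter sets."""

    name: str
    t_end: float
    record_every: float
    premolar: RDParameters
    molar: RDParameters
    raw: dict

    def with_seed(self, seed: int) -> "SimulationConfig":
        """Same configuration with both cascades reseeded (seed, seed + 1)."""
        from dataclasses import replace
        return SimulationConfig(
            name=self.name, t_end=self.t_end, record_every=self.record_every,
            premolar=replace(self.premolar, seed=seed),
            molar=replace(self.molar, seed=seed + 1),
            raw=self.raw)


def _growth_from_dict(d: dict) -> GrowthSchedule:
    stage0 = float(d.get("stage0", 19.0))
    tps = float(d.get("time_per_stage", 25.0))
    points = []
    for stage, rate_per_stage in d.get("schedule", [[stage0, 0.0]]):
        points.append(((float(stage) - stage0) * tps, float(rate_per_stage) / tps))
    return GrowthSchedule(
        points=tuple(points),
        mode=d.get("mode", "apical"),
        direction=d.get("direction", "anterior"),
        growth_end=d.get("growth_end", "right"),
    )


def params_from_dict(d: dict, cascade: str) -> RDParameters:
    """Build one cascade's RDParameters from its config block."""
    kin_block = dict(d.get("kinetics", {"name": "schnakenberg"}))
    kin_name = kin_block.pop("name", "schnakenberg")
    kinetics = get_kinetics(kin_name, **kin_block)
    grid = Grid(**d.get("grid", {}))
    detection = Detection(**d.get("detection", {}))
    gradient = GradientSpec(**d.get("gradient", {"shape": "none"}))
    growth = _growth_from_dict(d.get("growth", {}))
    return RDParameters(
        D_u=float(d.get("D_u", 1.0)),
        D_v=float(d.get("D_v", 40.0)),
        kinetics=kinetics,
        growth=growth,
        gradient=gradient,
        grid=grid,
        detection=detection,
        seed=int(d.get("seed", 0)),
        noise_amplitude=float(d.get("noise_amplitude", 1e-3)),
        bud_amplitude=float(d.get("bud_amplitude", 0.5)),
        bud_width_cells=float(d.get("bud_width_cells", 5.0)),
        bud_offset=float(d.get("bud_offset", 0.0)),
        cascade=cascade,
    )


def config_from_dict(raw: dict, name: str | None = None) -> SimulationConfig:
    missing = [k for k in ("premolar", "molar") if k not in raw]
    if missing:
        raise ValueError(f"simulation config missing cascade blocks {missing}")
    return SimulationConfig(
        name=name or raw.get("name", "unnamed"),
        t_end=float(raw.get("t_end", 120.0)),
        record_every=float(raw.get("record_every", 0.5)),
        premolar=params_from_dict(raw["premolar"], "premolar"),
        molar=params_from_dict(raw["molar"], "molar"),
        raw=raw,
    )


def load_config(name_or_path) -> SimulationConfig:
    """Load a simulation config by shipped preset name or filesystem path."""
    name_or_path = str(name_or_path)
    if name_or_path in SHIPPED:
        text = (resources.files("dentalcascade") / "configs"
                / f"{name_or_path}.yaml").read_text()
        raw = yaml.safe_load(text)
        return config_from_dict(raw, name=name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"no shipped config or file named {name_or_path!r} "
            f"(shipped: {', '.join(SHIPPED)})")
    raw = yaml.safe_load(path.read_text())
    return config_from_dict(raw, name=raw.get("name", path.stem))


def load_generator_spec(path) -> dict:
    """Load a synthetic-generator spec file (YAML mapping of overrides)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("generator spec file must contain a YAML mapping")
    for key in ("ic_ratio_range", "off_ic_base_range", "off_ic_inflation_range",
                "sides", "embryo_stages"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "embryo_rates_um_per_stage" in raw:
        raw["embryo_rates_um_per_stage"] = {
            k: tuple(v) for k, v in raw["embryo_rates_um_per_stage"].items()}
    return raw
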