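"""Case configuration: a single YAML document mapped 1:1 onto dataclasses.

Unknown keys are rejected so that typos fail loudly.  Every geometric,
fluid, boundary-condition and solver parameter of a study is addressable
here; the built-in geometry variants reproduce the three test articles
(blank housing, 1.09 mm blades, filleted 1.62 mm blades) as stand-ins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometrySpec, MeshSizing
from .solver import FluidProperties, SolverParams
from .transport import TransportParams


@dataclass
class DyeSpec:
    """Virtual-dye release: cube side (cm), center, washout threshold."""

    center: tuple = (0.0, 0.0, 0.0)
    side: float = 3.5
    threshold: float = 0.01


#: Geometry overrides for the three standard test articles.
VARIANTS = {
    "blank": {"obstacle": "none"},
    "vip109": {"obstacle": "biconical", "blade_height": 0.109,
               "fillets": False},
    "vip162": {"obstacle": "biconical", "blade_height": 0.162,
               "fillets": True},
}


@dataclass
class CaseConfig:
    """Full description of a simulation campaign."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    sizing: MeshSizing = field(default_factory=MeshSizing)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    solver: SolverParams = field(default_factory=SolverParams)
    transport: TransportParams = field(default_factory=TransportParams)
    dye: DyeSpec = field(default_factory=DyeSpec)
    cardiac_outputs: tuple = (3.0, 5.0, 7.0, 9.0, 11.0)   # L/min
    ivc_fraction: float = 0.6
    outlet_resistances: dict = field(default_factory=lambda: {
        "outlet_rpa": 204.51, "outlet_lpa": 222.49})
    variants: tuple = ("blank", "vip109", "vip162")
    run_transport: bool = True
    save_fields: bool = False
    output_dir: str = "fontanflow_out"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.ivc_fraction < 1.0):
            raise ValueError("ivc_fraction must lie in (0, 1)")
        if any(co <= 0 for co in self.cardiac_outputs):
            raise ValueError("cardiac outputs must be positive")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown geometry variants {sorted(unknown)}")

    def variant_geometry(self, name: str) -> GeometrySpec:
        base = dataclasses.asdict(self.geometry)
        base.pop("secondary_gap", None)
        sg = self.geometry.secondary_gap
        base.update(VARIANTS[name])
        return GeometrySpec(secondary_gap=sg, **base)


_NESTED = {
    "geometry": GeometrySpec,
    "sizing": MeshSizing,
    "fluid": FluidProperties,
    "solver": SolverParams,
    "transport": TransportParams,
    "dye": DyeSpec,
}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {context}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) and k not in (
            "outlet_resistances",) else v
    return cls(**coerced)


def load_config(path) -> CaseConfig:
    """Read a YAML case configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    top = {}
    for key, val in raw.items():
        if key in _NESTED:
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            top[key] = _build(_NESTED[key], val, key)
        else:
            top[key] = val
    return _build(CaseConfig, top, "top level")


def dump_config(cfg: CaseConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_hash(cfg: CaseConfig) -> str:
    import hashlib
    import json
    data = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(data.encode()).hexdigest()[:16]
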