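"""Run configuration: a strict YAML schema covering every module.

An empty file (or no file) yields the reference defaults: the metal-coated
50-nm SiN / 15-nm Ni / 10-nm Au film, a 4-kV 3-nm 31.3-pA beam scanning
1280x1024 px in 40 s, 10^5 transport electrons, the 7.5-permittivity
capacitor model, and the 9x9/sigma-1 filter with 12 deconvolution
iterations.  Unknown keys are rejected by name so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .charging import CapacitorModel
from .errors import ConfigError, DomainError, FilmSemError
from .materials import (
    ELEMENTS,
    BeamSpec,
    FilmStack,
    Layer,
    Material,
    get_material,
)
from .pipeline import DEFAULT_WEIGHT_WIDE, PSF_PRESETS
from .transport import TransportConfig


@dataclass(frozen=True)
class PipelineParams:
    """Parameters of the invert/smooth/deconvolve chain."""

    filter_size: int = 9
    filter_sigma: float = 1.0
    psf_preset: str | None = "baculovirus"
    psf_size: int = 241
    sigma_narrow: float | None = None  # overrides the preset when given
    sigma_wide: float | None = None
    weight_wide: float = DEFAULT_WEIGHT_WIDE
    iterations: int = 12

    def __post_init__(self) -> None:
        if self.psf_preset is not None and self.psf_preset.lower() not in PSF_PRESETS:
            raise DomainError(
                f"unknown PSF preset {self.psf_preset!r}; "
                f"choose from {sorted(PSF_PRESETS)}"
            )
        if (self.sigma_narrow is None) != (self.sigma_wide is None):
            raise DomainError("give both sigma_narrow and sigma_wide or neither")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for every subcommand."""

    stack: FilmStack
    beam: BeamSpec
    transport: TransportConfig
    capacitor: CapacitorModel
    target_potential: float
    pipeline: PipelineParams
    seed: int
    output_dir: str

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "target_potential": self.target_potential,
            "stack": [
                {
                    "material": l.material.name,
                    "thickness": l.thickness,
                }
                for l in self.stack.layers
            ],
            "materials": {
                l.material.name: {
                    "density": l.material.density,
                    # ordered pairs, not a mapping: YAML dumps mappings with
                    # sorted keys, which would reorder the composition
                    "composition": [
                        [e.symbol, w] for e, w in l.material.composition
                    ],
                }
                for l in self.stack.layers
            },
            "beam": asdict(self.beam),
            "transport": asdict(self.transport),
            "capacitor": asdict(self.capacitor),
            "pipeline": asdict(self.pipeline),
        }


_TOP_KEYS = {
    "seed",
    "output_dir",
    "target_potential",
    "stack",
    "materials",
    "beam",
    "transport",
    "capacitor",
    "pipeline",
}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )


def _build_materials(raw: dict) -> dict[str, Material]:
    out: dict[str, Material] = {}
    for name, spec in (raw or {}).items():
        _check_keys(f"materials.{name}", spec, {"density", "composition"})
        comp_raw = spec.get("composition", {})
        pairs = comp_raw.items() if isinstance(comp_raw, dict) else comp_raw
        comp = []
        for symbol, w in pairs:
            if symbol not in ELEMENTS:
                raise ConfigError(
                    f"unknown element {symbol!r} in material {name!r}; "
                    f"known: {sorted(ELEMENTS)}"
                )
            comp.append((ELEMENTS[symbol], float(w)))
        try:
            out[name] = Material(name, float(spec.get("density", 0.0)), tuple(comp))
        except DomainError as exc:
            raise ConfigError(f"material {name!r}: {exc}") from exc
    return out


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    ``path=None`` or an empty file returns the reference defaults.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    _check_keys("<root>", raw, _TOP_KEYS)

    custom = _build_materials(raw.get("materials", {}))

    def lookup(name: str) -> Material:
        if name in custom:
            return custom[name]
        try:
            return get_material(name)
        except DomainError as exc:
            raise ConfigError(str(exc)) from exc

    stack_raw = raw.get(
        "stack",
        [
            {"material": "SiN", "thickness": 50.0},
            {"material": "Ni", "thickness": 15.0},
            {"material": "Au", "thickness": 10.0},
        ],
    )
    layers = []
    for i, layer in enumerate(stack_raw):
        _check_keys(f"stack[{i}]", layer, {"material", "thickness"})
        if "material" not in layer or "thickness" not in layer:
            raise ConfigError(f"stack[{i}] needs 'material' and 'thickness'")
        try:
            layers.append(Layer(lookup(str(layer["material"])), float(layer["thickness"])))
        except DomainError as exc:
            raise ConfigError(f"stack[{i}]: {exc}") from exc

    seed = int(raw.get("seed", 0))

    def build(section, cls, defaults_key_map=None, **extra):
        given = raw.get(section, {}) or {}
        fields = {f for f in cls.__dataclass_fields__}
        _check_keys(section, given, fields)
        try:
            return cls(**{**given, **extra})
        except (DomainError, TypeError) as exc:
            raise ConfigError(f"section {section!r}: {exc}") from exc

    beam = build("beam", BeamSpec)

    transport_raw = dict(raw.get("transport", {}) or {})
    _check_keys("transport", transport_raw, set(TransportConfig.__dataclass_fields__))
    transport_raw.setdefault("rng_seed", seed)
    try:
        transport = TransportConfig(**transport_raw)
    except (DomainError, TypeError) as exc:
        raise ConfigError(f"section 'transport': {exc}") from exc

    cap_raw = dict(raw.get("capacitor", {}) or {})
    _check_keys(
        "capacitor",
        cap_raw,
        set(CapacitorModel.__dataclass_fields__) | {"target_potential"},
    )
    target_v = float(
        cap_raw.pop("target_potential", raw.get("target_potential", 400.0))
    )
    try:
        capacitor = CapacitorModel(**cap_raw)
    except (DomainError, TypeError) as exc:
        raise ConfigError(f"section 'capacitor': {exc}") from exc

    pipeline = build("pipeline", PipelineParams)

    try:
        stack = FilmStack(tuple(layers))
    except DomainError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        stack=stack,
        beam=beam,
        transport=transport,
        capacitor=capacitor,
        target_potential=target_v,
        pipeline=pipeline,
        seed=seed,
        output_dir=str(raw.get("output_dir", ".")),
    )


def dump_config(config: RunConfig) -> str:
    """Serialize a RunConfig back to YAML; ``load`` of the dump reproduces
    the config exactly."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
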