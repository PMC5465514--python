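"""Run configuration: one YAML file with per-command sections.

Every numeric default traces to a stated model constant where one exists
(cell step 0.02 ms, D_global 0.154 mm^2/ms, 0.33 mm spacing, xi 0.33 mm,
RV scaling (2, 4), potential color anchors -86.0 / 45.0 mV). Unknown keys
are rejected so typos cannot silently fall back to defaults, and a parsed
config round-trips through serialization unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "PhantomSection", "CellSection", "TissueSection",
           "ProtocolSection", "RenderSection", "OutputSection"]


def _from_dict(cls, data: dict, where: str):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ValueError(f"section '{where}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in section '{where}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            val = data[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


def _to_dict(obj):
    out = {}
    for f in dataclasses.fields(obj):
        val = getattr(obj, f.name)
        if isinstance(val, tuple):
            val = list(val)
        out[f.name] = val
    return out


@dataclass(frozen=True)
class PhantomSection:
    dims: tuple = (60, 60, 80)
    spacing: float = 0.33          # mm, isotropic
    seed: int = 0
    jitter_amplitude: float = 0.02
    input_volume: str | None = None  # path to an existing anatomy NRRD instead


@dataclass(frozen=True)
class CellSection:
    cell_class: str = "epi"        # endo | mid | epi
    dt: float = 0.02               # ms, cell-integration step
    # multiplicative conductance scalings relative to the published values
    g_Kr_scale: float = 1.0
    g_Ks_scale: float = 1.0
    g_CaL_scale: float = 1.0
    g_to_scale: float = 1.0
    # absolute overrides by conductance name (g_Na, g_K1, ..., applied last)
    conductances: dict | None = None


@dataclass(frozen=True)
class TissueSection:
    D_global: float = 0.154        # mm^2/ms
    xi: float = 0.33               # phase-field interface constant, mm
    phase_iterations: int | None = None  # default: pseudo-time 1.0
    # optional per-tissue-class diffusion override, class name -> mm^2/ms
    D_per_class: dict | None = None


@dataclass(frozen=True)
class ProtocolSection:
    style: str = "single"          # single | S1S2
    s1_region: str = "apex"        # named phantom mask or 'slab_edge'
    s2_region: str = "lv_endo"
    onset: float = 0.0             # ms
    stim_duration: float = 2.0     # ms
    amplitude: float = -52.0       # pA/pF (negative depolarizes)
    coupling_interval: float = 120.0  # ms, S1->S2 (S1S2 style only)
    duration: float = 70.0         # ms, total simulated time
    snapshot_interval: float = 10.0  # ms


@dataclass(frozen=True)
class RenderSection:
    image_size: tuple = (128, 128)
    view_dir: tuple = (0.0, 1.0, 0.0)
    up: tuple = (0.0, 0.0, 1.0)
    step: float = 0.15             # mm, ray step (<= half voxel spacing)
    mode: str = "merged"           # ltm_anatomy | ltm_potential | merged
    background: tuple = (0.0, 0.0, 0.0)
    potential_alpha: float = 0.9


@dataclass(frozen=True)
class OutputSection:
    directory: str = "out"
    overwrite: bool = False


_SECTIONS = {
    "phantom": PhantomSection,
    "cell": CellSection,
    "tissue": TissueSection,
    "protocol": ProtocolSection,
    "render": RenderSection,
    "output": OutputSection,
}


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    cell: CellSection = field(default_factory=CellSection)
    tissue: TissueSection = field(default_factory=TissueSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    render: RenderSection = field(default_factory=RenderSection)
    output: OutputSection = field(default_factory=OutputSection)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = data or {}
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**{name: _from_dict(section_cls, data.get(name), name)
                      for name, section_cls in _SECTIONS.items()})

    def to_dict(self) -> dict:
        return {name: _to_dict(getattr(self, name)) for name in _SECTIONS}

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
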