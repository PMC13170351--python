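"""Run configuration: one flat TOML file with per-module sections.

Defaults are the analysis thresholds of the method: variant frequency
>= 1% at the cascade, minimum coverage 4 and count 2 at initial calling,
base-quality neighborhood 5/30/30, consensus across >= 2 replicates, and
17/37-nt structure windows.  Unknown keys are rejected, not warned — a
silently ignored typo in a threshold would corrupt scientific output.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .calling import CallParams, StrandFilterParams
from .pileup import QualityFilterParams
from .readprep import MergeParams
from .simdata import SimConfig


@dataclass(frozen=True)
class TrimParams:
    quality_limit: float = 0.01
    min_len: int = 50
    max_len: int = 150
    max_ambiguities: int = 1


@dataclass(frozen=True)
class ConsensusParams:
    min_shared: int = 2


@dataclass(frozen=True)
class WindowParams:
    short_window: int = 17
    long_window: int = 37
    anchor: str = "arm"  # arm | center
    min_stem: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    genome: str = ""
    annotation: str = ""
    sample_sheet: str = ""
    outdir: str = "editscan_out"
    sim: SimConfig = field(default_factory=SimConfig)
    trim: TrimParams = field(default_factory=TrimParams)
    merge: MergeParams = field(default_factory=MergeParams)
    quality: QualityFilterParams = field(default_factory=QualityFilterParams)
    call: CallParams = field(default_factory=CallParams)
    strand_filter: StrandFilterParams = field(default_factory=StrandFilterParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    windows: WindowParams = field(default_factory=WindowParams)


_SECTIONS = {
    "sim": SimConfig,
    "trim": TrimParams,
    "merge": MergeParams,
    "quality": QualityFilterParams,
    "call": CallParams,
    "strand_filter": StrandFilterParams,
    "consensus": ConsensusParams,
    "windows": WindowParams,
}
_TOP_KEYS = ("seed", "genome", "annotation", "sample_sheet", "outdir")


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    return repr(value)


def serialize(cfg: RunConfig) -> str:
    lines = [f"{k} = {_fmt(getattr(cfg, k))}" for k in _TOP_KEYS]
    for section, cls in _SECTIONS.items():
        lines.append("")
        lines.append(f"[{section}]")
        obj = getattr(cfg, section)
        for f in dataclasses.fields(cls):
            lines.append(f"{f.name} = {_fmt(getattr(obj, f.name))}")
    return "\n".join(lines) + "\n"


def parse(text: str) -> RunConfig:
    raw = tomllib.loads(text)
    kwargs = {}
    for key, value in raw.items():
        if key in _TOP_KEYS:
            kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = cls(**coerced)
        else:
            raise ValueError(f"unknown config key or section: {key!r}")
    return RunConfig(**kwargs)


def load(path) -> RunConfig:
    return parse(Path(path).read_text())


def save(cfg: RunConfig, path) -> None:
    Path(path).write_text(serialize(cfg))
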