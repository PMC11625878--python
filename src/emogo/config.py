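"""Run configuration: one serializable document holding every tunable.

``RunConfig`` nests the task, generator, preprocessing, ERP and stats
parameter blocks and round-trips through YAML (write then read yields an
equal config), so a study run can be reproduced from its config snapshot
plus seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
import typing

import yaml

from emogo.synth import GeneratorParams
from emogo.task import TaskSpec


@dataclass(frozen=True)
class PreprocessParams:
    bp_low_hz: float = 0.3
    bp_high_hz: float = 100.0
    lp_cutoff_hz: float = 30.0
    threshold_uv: float = 200.0
    pad_ms: float = 100.0
    blink_min_rise_ms: float = 100.0
    blink_min_fall_ms: float = 150.0
    blink_min_amp_uv: float = 125.0
    blink_prescreen_uv: float = 40.0

    def __post_init__(self) -> None:
        for name in ("bp_low_hz", "bp_high_hz", "lp_cutoff_hz", "threshold_uv",
                     "blink_min_rise_ms", "blink_min_fall_ms", "blink_min_amp_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ErpParams:
    tmin_ms: float = -100.0
    tmax_ms: float = 1000.0
    n2_window_ms: tuple[float, float] = (300.0, 400.0)
    p3_window_ms: tuple[float, float] = (480.0, 600.0)
    channel: str = "Fz"
    correct_only: bool = True
    min_trials: int = 3
    min_accuracy: float = 50.0
    anticipatory_rt_ms: float = 200.0


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    transform_rcads: bool = True     # Log10(+1) before correlation/regression
    transform_cheat: bool = False
    erp_covariates: tuple[str, ...] = ("age",)
    behavior_covariates: tuple[str, ...] = ("gender_male",)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    task: TaskSpec = field(default_factory=TaskSpec)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    erp: ErpParams = field(default_factory=ErpParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def resolved_generator(self) -> GeneratorParams:
        """Generator params with the run seed and task spec applied."""
        return dataclasses.replace(self.generator, seed=self.seed, task=self.task)


# ---------------------------------------------------------------------------
# dataclass <-> plain-document conversion (YAML-safe)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(tp, value):
    origin = typing.get_origin(tp)
    if is_dataclass(tp) and isinstance(value, dict):
        kwargs = {}
        hints = typing.get_type_hints(tp)
        for f in dataclasses.fields(tp):
            if f.name in value:
                kwargs[f.name] = _from_plain(hints[f.name], value[f.name])
        return tp(**kwargs)
    if origin in (tuple,) and isinstance(value, (list, tuple)):
        args = typing.get_args(tp)
        if len(args) == 2 and args[1] is Ellipsis:
            return tuple(_from_plain(args[0], v) for v in value)
        if args:
            return tuple(_from_plain(a, v) for a, v in zip(args, value))
        return tuple(value)
    if origin in (frozenset, set) and isinstance(value, (list, tuple)):
        return frozenset(value)
    if tp is float and value is not None:
        return float(value)
    if tp is int and value is not None:
        return int(value)
    return value


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(doc: dict) -> RunConfig:
    return _from_plain(RunConfig, doc)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False), encoding="utf-8")
    return path


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return config_from_dict(doc or {})
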