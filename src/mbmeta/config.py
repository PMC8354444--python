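"""Run configuration: YAML/JSON round-trip into the typed config objects.

A run config has four blocks (task, train, loss, analysis is implicit in
the CLI commands) plus a seed and an output directory.  Unknown keys are
rejected so typos fail loudly; the resolved config is written next to
every artifact together with its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metalearn.losses import LossConfig
from .metalearn.train import TaskMix, TrainConfig
from .navigation import NavOptions
from .plasticity import PlasticityConfig
from .tasks import ConditioningOptions

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/latest"
    task: TaskMix = field(default_factory=TaskMix)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig | None = None


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path or cls.__name__}")
    return data


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) run config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top = _build(RunConfig, raw, "top level")

    task_d = dict(top.get("task", {}) or {})
    opts_d = task_d.pop("options", {}) or {}
    nav_d = task_d.pop("nav_options", {}) or {}
    task = TaskMix(**_build(TaskMix, task_d, "task"),
                   options=ConditioningOptions(
                       **_build(ConditioningOptions, opts_d, "task.options")),
                   nav_options=NavOptions(
                       **_build(NavOptions, nav_d, "task.nav_options")))
    if "paradigms" in task_d:
        task.paradigms = tuple(task_d["paradigms"])

    train_d = dict(top.get("train", {}) or {})
    pl_d = train_d.pop("plasticity", None)
    train = TrainConfig(**_build(TrainConfig, train_d, "train"),
                        plasticity=None if pl_d is None else PlasticityConfig(
                            **_build(PlasticityConfig, pl_d,
                                     "train.plasticity")))

    loss_d = top.get("loss")
    loss = None if loss_d is None else LossConfig(
        **_build(LossConfig, dict(loss_d), "loss"))
    return RunConfig(seed=int(top.get("seed", 0)),
                     output_dir=str(top.get("output_dir", "runs/latest")),
                     task=task, train=train, loss=loss)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
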