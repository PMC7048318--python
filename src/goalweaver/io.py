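"""Config files, run manifests and result serialisation."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone

import yaml

from .task import TaskConfig


def load_config(path) -> tuple[TaskConfig, dict[str, tuple[int, int]]]:
    """Read a YAML/JSON config with ``task.{n_trials,threshold,reward_one,
    reward_both}`` and ``conditions.<name>.initial_pts`` entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    task = TaskConfig(**raw.get("task", {}))
    conditions = {
        name: tuple(entry["initial_pts"])
        for name, entry in raw.get("conditions", {}).items()
    }
    return task, conditions


def save_config(path, config: TaskConfig,
                conditions: dict[str, tuple[int, int]]) -> None:
    payload = {
        "task": {"n_trials": config.n_trials, "threshold": config.threshold,
                 "reward_one": config.reward_one,
                 "reward_both": config.reward_both,
                 "point_min": config.point_min, "point_max": config.point_max},
        "conditions": {k: {"initial_pts": list(v)} for k, v in conditions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_manifest(path, inputs: dict, seeds: dict) -> None:
    """Record what a run saw: inputs, seeds, package and platform versions."""
    from . import __version__
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "goalweaver_version": __version__,
        "python": platform.python_version(),
        "inputs": inputs,
        "seeds": seeds,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
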