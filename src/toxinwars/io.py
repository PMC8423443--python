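"""Configuration handling and output serialisation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import CompetitionOutcome, Trajectory
from .params import EcologicalParams
from .strategies import Strategy

TRAJECTORY_HEADER = "t,C_A,C_B,T_A,T_B,N,f_A,f_B"


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """One row per solver step, floats at 10 significant digits."""
    cols = [trajectory.t, trajectory.C_A, trajectory.C_B, trajectory.T_A,
            trajectory.T_B, trajectory.N, trajectory.f_A, trajectory.f_B]
    with open(path, "w") as fh:
        fh.write(TRAJECTORY_HEADER + "\n")
        for row in zip(*cols):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def outcome_to_dict(outcome: CompetitionOutcome) -> dict:
    return {
        "final_biomass_A": outcome.final_biomass_A,
        "final_biomass_B": outcome.final_biomass_B,
        "extinct_A": outcome.extinct_A,
        "extinct_B": outcome.extinct_B,
        "local_winner": outcome.local_winner,
    }


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def apply_overrides(cfg: dict, overrides) -> dict:
    """Apply dotted ``section.key=value`` overrides onto a config dict."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like section.key=value: {item}")
        dotted, raw = item.split("=", 1)
        keys = dotted.split(".")
        value = yaml.safe_load(raw)
        node = cfg
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot override through scalar at {k!r}")
        node[keys[-1]] = value
    return cfg


def params_from_config(cfg: dict) -> EcologicalParams:
    """Build solver parameters from the ``ecology`` + ``solver`` sections."""
    merged = {}
    merged.update(cfg.get("ecology") or {})
    solver = cfg.get("solver") or {}
    allowed_solver = {"dt", "t_end", "extinction_threshold", "clamp_threshold"}
    unknown = set(solver) - allowed_solver
    if unknown:
        raise ValueError(f"unknown solver keys: {sorted(unknown)}")
    merged.update(solver)
    return EcologicalParams.from_dict(merged)


def strategy_from_config(cfg: dict, key: str) -> Strategy:
    section = cfg.get(key)
    if section is None:
        raise ValueError(f"config is missing the {key!r} section")
    return Strategy.from_dict(section)


def dump_resolved_config(cfg: dict, params: EcologicalParams,
                         outdir: Path, seed: Optional[int] = None) -> None:
    resolved = dict(cfg)
    resolved["resolved_ecology"] = params.to_dict()
    if seed is not None:
        resolved["seed"] = seed
    with open(Path(outdir) / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
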