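"""Run configuration, (de)serialization helpers, and the solver benchmark.

A single YAML file configures every stage (the three SVMs share the ray
geometry, so one source of truth avoids silent mismatches).  Defaults
reproduce the reference operating point: m=36 rays, varsigma=1, windows
200x200 and 30x15, C=10 for all three SVMs, thresholds theta=2
(pre-screening) and theta=-1.5 (classification), minimum glomerulus
diameter 50 px.  Unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, get_args, get_origin

import numpy as np
import pandas as pd
import yaml

from . import mplp as mplp_mod
from . import solver as solver_mod
from .pipeline import DetectionConfig
from .synthetic import SceneParams, generate_boundary_problem


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class BenchConfig:
    """Random-instance source for the solver benchmark."""

    n_instances: int = 100
    m: int = 36
    n: int = 22
    varsigma: int = 1
    mplp_max_iters: int = 2000
    include_mplp: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: detection + scene generation + solver."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    scene: SceneParams = field(default_factory=SceneParams)
    bench: BenchConfig = field(default_factory=BenchConfig)
    seed: int = 0
    out_dir: str = "."


def _build(cls, data: Any, path: str):
    """Recursively construct a dataclass from nested dicts, rejecting
    unknown keys; sequences are coerced to the annotated tuple types."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key '{path + '.' if path else ''}{sorted(unknown)[0]}'")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        ftype = f.type if not isinstance(f.type, str) else None
        target = _field_dataclass(cls, name)
        where = f"{path + '.' if path else ''}{name}"
        if target is not None:
            kwargs[name] = _build(target, value, where)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def _field_dataclass(cls, name: str):
    """Return the dataclass type of field ``name``, if it is one."""
    import typing

    hints = typing.get_type_hints(cls)
    t = hints.get(name)
    if t is None:
        return None
    if get_origin(t) is not None:  # Optional, tuple, ...
        for arg in get_args(t):
            if is_dataclass(arg):
                return arg
        return None
    return t if is_dataclass(t) else None


def config_to_dict(obj) -> Any:
    """Dataclass tree -> plain dict/list/scalars (lossless round-trip)."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: config_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [config_to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; an empty/missing body means defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("top level of the config must be a mapping")
            data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return _build(RunConfig, data, "")


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


# --------------------------------------------------------------------------
# serialization of polygons / detections / truth


def polygon_to_json(polygon: np.ndarray) -> list[list[float]]:
    return [[float(r), float(c)] for r, c in np.asarray(polygon, dtype=float)]


def detections_to_json(detections) -> str:
    return json.dumps(
        [
            {
                "center": [float(d.center[0]), float(d.center[1])],
                "polygon": polygon_to_json(d.polygon),
                "score": float(d.score),
                "accepted": bool(d.accepted),
            }
            for d in detections
        ],
        indent=2,
    )


def truth_to_json(truth) -> str:
    return json.dumps(
        {
            "centers": [[float(g.center[0]), float(g.center[1])] for g in truth.glomeruli],
            "polygons": [polygon_to_json(g.polygon()) for g in truth.glomeruli],
            "diameters": [float(g.diameter) for g in truth.glomeruli],
        },
        indent=2,
    )


def problem_to_json(prob) -> str:
    return json.dumps({"m": prob.m, "n": prob.n, "varsigma": prob.varsigma,
                       "L": prob.L.ravel().tolist()})


def problem_from_json(text: str):
    data = json.loads(text)
    L = np.asarray(data["L"], dtype=float).reshape(data["m"], data["n"])
    return solver_mod.BoundaryProblem(L=L, varsigma=int(data["varsigma"]))


# --------------------------------------------------------------------------
# solver benchmark


def bench_solvers(config: RunConfig | BenchConfig | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Run all solvers on random instances; one row per (instance, solver).

    Columns: instance, solver, objective, n_dp (chain-DP calls, or
    iterations for MPLP variants), feasible, converged.  All exact
    solvers agree on the objective by construction; the table makes that
    auditable.
    """
    if isinstance(config, RunConfig):
        bench, base_seed = config.bench, config.seed
    else:
        bench, base_seed = config or BenchConfig(), 0
    if seed is not None:
        base_seed = seed
    rows = []
    for k in range(bench.n_instances):
        prob = generate_boundary_problem(bench.m, bench.n, bench.varsigma,
                                         seed=base_seed + k)
        for scheme in solver_mod.SCHEMES:
            rep = solver_mod.dcdp(prob, scheme)
            rows.append(dict(instance=k, solver=f"dcdp_{scheme}",
                             objective=rep.solution.objective, n_dp=rep.n_dp,
                             feasible=rep.solution.feasible, converged=True))
        rep = solver_mod.edp(prob)
        rows.append(dict(instance=k, solver="edp", objective=rep.solution.objective,
                         n_dp=rep.n_dp, feasible=rep.solution.feasible, converged=True))
        if bench.include_mplp:
            for mode in mplp_mod.MODES:
                res = mplp_mod.mplp_solve(prob, mode, max_iters=bench.mplp_max_iters)
                rows.append(dict(instance=k, solver=mode,
                                 objective=res.solution.objective,
                                 n_dp=res.iterations,
                                 feasible=res.solution.feasible,
                                 converged=res.converged))
    return pd.DataFrame(rows)
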