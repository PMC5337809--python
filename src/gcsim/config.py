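"""TOML configuration and run-directory I/O.

An empty config file yields the full default parameter set; any key can be
overridden.  Unknown keys are rejected with the offending key path so typos
never silently fall back to defaults.  Configs round-trip losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .params import (
    AffinityChangeParams,
    ModelParams,
    MutationTreeParams,
    ParameterError,
    RateParams,
    ScheduleParams,
    SignalParams,
)

__all__ = ["RunConfig", "load_config", "save_config", "params_hash",
           "save_run_dir", "load_run_dir"]

_GROUPS = {
    "rates": RateParams,
    "signals": SignalParams,
    "mutation_tree": MutationTreeParams,
    "affinity": AffinityChangeParams,
    "schedule": ScheduleParams,
}
_TOP_KEYS = {"mutations_per_division", "subclone_level", "peptide_spawn_rule",
             "shm_sampling", "subunit_mutation_loss", "rtol", "atol"}


@dataclass(frozen=True)
class RunConfig:
    """Model parameters plus run plumbing (seeds, output directory)."""

    params: ModelParams = field(default_factory=ModelParams)
    seeds: tuple[int, ...] = (1,)
    outdir: str | None = None


def _build_group(name: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown key '{name}.{sorted(unknown)[0]}' in config")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ParameterError(f"bad value in [{name}]: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse a TOML config; every key optional, unknown keys rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    run = data.pop("run", {})
    unknown_run = set(run) - {"seeds", "outdir"}
    if unknown_run:
        raise ParameterError(f"unknown key 'run.{sorted(unknown_run)[0]}' in config")

    kwargs: dict = {}
    for name, cls in _GROUPS.items():
        group = data.pop(name, {})
        if not isinstance(group, dict):
            raise ParameterError(f"'{name}' must be a table")
        if name == "schedule" and "founder_affinities" in group:
            group["founder_affinities"] = tuple(group["founder_affinities"])
        kwargs[name] = _build_group(name, cls, group)
    top = {}
    for key in list(data):
        if key in _TOP_KEYS:
            top[key] = data.pop(key)
        else:
            raise ParameterError(f"unknown key '{key}' in config")
    params = ModelParams(**kwargs, **top)
    seeds = tuple(int(s) for s in run.get("seeds", (1,)))
    return RunConfig(params=params, seeds=seeds, outdir=run.get("outdir"))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig as TOML (inverse of :func:`load_config`)."""
    lines = []
    p = cfg.params
    for key in sorted(_TOP_KEYS):
        lines.append(f"{key} = {_toml_value(getattr(p, key))}")
    for name in _GROUPS:
        lines.append(f"\n[{name}]")
        for f in dataclasses.fields(getattr(p, name)):
            lines.append(f"{f.name} = {_toml_value(getattr(getattr(p, name), f.name))}")
    lines.append("\n[run]")
    lines.append(f"seeds = {_toml_value(list(cfg.seeds))}")
    if cfg.outdir is not None:
        lines.append(f"outdir = {_toml_value(cfg.outdir)}")
    Path(path).write_text("\n".join(lines) + "\n")


def params_hash(params: ModelParams) -> str:
    """Stable short hash identifying a parameter set."""
    blob = json.dumps(params.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_run_dir(result, outdir) -> None:
    """Write trajectory.csv, events.csv, params.toml and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trajectory.to_csv(outdir / "trajectory.csv", index=False)
    result.events.to_csv(outdir / "events.csv", index=False)
    save_config(RunConfig(params=result.params, seeds=(result.seed,)),
                outdir / "params.toml")
    manifest = {
        "seed": result.seed,
        "replicate": result.replicate,
        "extinct": result.extinct,
        "params_hash": params_hash(result.params),
        "gcsim_version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_run_dir(rundir):
    """Reload a saved run as a :class:`~gcsim.simulate.SimulationResult`."""
    import pandas as pd

    from .simulate import SimulationResult

    rundir = Path(rundir)
    manifest = json.loads((rundir / "manifest.json").read_text())
    cfg = load_config(rundir / "params.toml")
    return SimulationResult(
        seed=manifest["seed"],
        replicate=manifest.get("replicate", 0),
        params=cfg.params,
        trajectory=pd.read_csv(rundir / "trajectory.csv"),
        events=pd.read_csv(rundir / "events.csv"),
        extinct=manifest.get("extinct", False),
    )
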