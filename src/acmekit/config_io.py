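"""Model/solver configuration files (YAML or JSON) and run manifests.

The schema is deliberately small and strict: unknown keys are rejected with
the path of the offending key, and every rate is a text expression compiled
through the same whitelist as programmatic models, so a parsed model is fully
round-trippable (``emit_config(parse_config(p))`` re-parses to an equivalent
model).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grids import Grid, GridDensity
from .integrate import SolverSettings
from .model import (ACMEModel, ContinuumSpecies, CustomKernel, DiscreteState,
                    DiscreteTransition, ExponentialKernel, JumpProcess, Reaction,
                    UniformFragmentationKernel)

__all__ = ["parse_config", "emit_config", "save_config", "build_initial", "RunManifest", "write_manifest"]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"name", "species", "states", "parameters", "reactions", "jumps",
             "transitions", "omega", "diffusion", "allow_signed_rates", "solver", "initial"}
_SOLVER_KEYS = {"t_final", "method", "cfl_safety", "snapshot_times", "steady_tol",
                "max_steps", "limiter", "split_local_sinks", "record_every", "progress_every"}
_INITIAL_KEYS = {"type", "state", "x0", "expr", "centre", "width2", "normalize"}


def _reject_unknown(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path}")


def _kernel_from_config(spec: dict, path: str) -> ExponentialKernel | UniformFragmentationKernel | CustomKernel:
    _reject_unknown(spec, {"type", "mean", "expr", "support"}, path)
    kind = spec.get("type")
    if kind == "exponential":
        return ExponentialKernel(mean=float(spec["mean"]))
    if kind == "uniform_fragmentation":
        return UniformFragmentationKernel()
    if kind == "custom_expr":
        return CustomKernel(expr=spec["expr"], support=float(spec.get("support", np.inf)))
    raise ConfigError(f"unknown kernel type {kind!r} at {path}.type")


def _rate_from_config(spec, model: ACMEModel, path: str):
    if isinstance(spec, dict):
        _reject_unknown(spec, {"per_state"}, path)
        return model.compile_rate(dict(spec["per_state"]))
    if isinstance(spec, (str, int, float)):
        return model.compile_rate(spec)
    raise ConfigError(f"rate at {path} must be an expression or {{per_state: {{...}}}}")


def parse_config(path) -> tuple[ACMEModel, SolverSettings, dict]:
    """Parse a YAML/JSON model file into (model, solver settings, initial spec)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "$")

    diffusion = bool(raw.get("diffusion", False))
    omega = raw.get("omega")
    if diffusion and omega is None:
        raise ConfigError("missing required key $.omega (diffusion is enabled)")

    species = []
    for i, sp in enumerate(raw.get("species", [])):
        _reject_unknown(sp, {"name", "domain_max", "n_cells"}, f"$.species[{i}]")
        species.append(ContinuumSpecies(sp["name"], float(sp["domain_max"]), int(sp["n_cells"])))
    states = []
    for i, st in enumerate(raw.get("states", [])):
        _reject_unknown(st, {"label", "phantom", "absorbing"}, f"$.states[{i}]")
        states.append(DiscreteState(st["label"], bool(st.get("phantom", False)),
                                    bool(st.get("absorbing", False))))

    model = ACMEModel(
        species=species, states=states,
        omega=float(omega) if omega is not None else None,
        diffusion_enabled=diffusion,
        allow_signed_rates=bool(raw.get("allow_signed_rates", False)),
        parameters={k: float(v) for k, v in (raw.get("parameters") or {}).items()},
        name=raw.get("name", ""),
    )
    for i, rx in enumerate(raw.get("reactions", [])):
        p = f"$.reactions[{i}]"
        _reject_unknown(rx, {"displacement", "rate", "name"}, p)
        model.reactions.append(Reaction(tuple(int(c) for c in rx["displacement"]),
                                        _rate_from_config(rx["rate"], model, p + ".rate"),
                                        name=rx.get("name", "")))
    for i, jp in enumerate(raw.get("jumps", [])):
        p = f"$.jumps[{i}]"
        _reject_unknown(jp, {"direction", "rate", "kernel", "mode", "name"}, p)
        model.jumps.append(JumpProcess(tuple(int(c) for c in jp["direction"]),
                                       _rate_from_config(jp["rate"], model, p + ".rate"),
                                       _kernel_from_config(jp["kernel"], p + ".kernel"),
                                       jp.get("mode", "probability"),
                                       name=jp.get("name", "")))
    for i, tr in enumerate(raw.get("transitions", [])):
        p = f"$.transitions[{i}]"
        _reject_unknown(tr, {"from", "to", "rate"}, p)
        model.transitions.append(DiscreteTransition(tr["from"], tr["to"],
                                                    model.compile_rate(tr["rate"])))

    solver_raw = dict(raw.get("solver") or {})
    _reject_unknown(solver_raw, _SOLVER_KEYS, "$.solver")
    if "snapshot_times" in solver_raw:
        solver_raw["snapshot_times"] = tuple(float(v) for v in solver_raw["snapshot_times"])
    settings = SolverSettings(**solver_raw)

    initial = dict(raw.get("initial") or {"type": "uniform"})
    _reject_unknown(initial, _INITIAL_KEYS, "$.initial")
    return model, settings, initial


def build_initial(model: ACMEModel, spec: dict) -> GridDensity:
    """Realise an initial-condition spec on the model grid."""
    from .case_studies import delta_initial, uniform_initial

    kind = spec.get("type", "uniform")
    state = spec.get("state")
    if kind == "uniform":
        return uniform_initial(model, state)
    if kind == "delta":
        return delta_initial(model, float(spec["x0"]), state)
    if kind == "gaussian":
        grid = Grid.from_species(model.species)
        c, w2 = float(spec.get("centre", 0.1)), float(spec.get("width2", 1e-3))
        p = GridDensity.zeros(grid, model.state_labels)
        k = p.index(state) if state else 0
        x = grid.coords()[0]
        p.values[k] = np.exp(-((x - c) ** 2) / w2) / np.sqrt(np.pi * w2)
        if spec.get("normalize", True):
            p.values[k] /= p.total_mass()
        return p
    if kind == "expr":
        grid = Grid.from_species(model.species)
        rate = model.compile_rate(spec["expr"])
        p = GridDensity.zeros(grid, model.state_labels)
        k = p.index(state) if state else 0
        p.values[k] = rate(grid.coords(), 0.0)
        if spec.get("normalize", True):
            p.values[k] /= p.total_mass()
        return p
    raise ConfigError(f"unknown initial-condition type {kind!r}")


def _rate_to_config(rate, path: str):
    if isinstance(rate, dict):
        out = {}
        for lbl, rf in rate.items():
            if rf.expression is None:
                raise ConfigError(f"rate {path}.{lbl} has no expression; cannot serialise")
            out[lbl] = rf.expression
        return {"per_state": out}
    if rate.expression is None:
        raise ConfigError(f"rate {path} has no expression; cannot serialise")
    return rate.expression


def emit_config(model: ACMEModel, settings: SolverSettings | None = None,
                initial: dict | None = None) -> dict:
    """Serialise a model (and optionally solver/initial blocks) to plain data."""
    out: dict = {}
    if model.name:
        out["name"] = model.name
    out["species"] = [{"name": s.name, "domain_max": s.domain_max, "n_cells": s.n_cells}
                      for s in model.species]
    out["states"] = [
        {k: v for k, v in (("label", s.label), ("phantom", s.is_phantom),
                           ("absorbing", s.is_absorbing)) if k == "label" or v}
        for s in model.states
    ]
    if model.parameters:
        out["parameters"] = dict(model.parameters)
    if model.reactions:
        out["reactions"] = [
            {"displacement": list(rx.displacement),
             "rate": _rate_to_config(rx.rate, f"reactions[{i}]"),
             **({"name": rx.name} if rx.name else {})}
            for i, rx in enumerate(model.reactions)
        ]
    if model.jumps:
        out["jumps"] = [
            {"direction": list(jp.direction),
             "rate": _rate_to_config(jp.rate, f"jumps[{i}]"),
             "kernel": {"type": jp.kernel.kind, **jp.kernel.params()},
             "mode": jp.multiplicity_mode,
             **({"name": jp.name} if jp.name else {})}
            for i, jp in enumerate(model.jumps)
        ]
    if model.transitions:
        out["transitions"] = [
            {"from": tr.from_state, "to": tr.to_state,
             "rate": _rate_to_config(tr.rate, f"transitions[{i}]")}
            for i, tr in enumerate(model.transitions)
        ]
    if model.omega is not None:
        out["omega"] = model.omega
    out["diffusion"] = model.diffusion_enabled
    if model.allow_signed_rates:
        out["allow_signed_rates"] = True
    if settings is not None:
        s = asdict(settings)
        s["snapshot_times"] = list(s["snapshot_times"])
        out["solver"] = s
    if initial is not None:
        out["initial"] = dict(initial)
    return out


def save_config(model: ACMEModel, path, settings: SolverSettings | None = None,
                initial: dict | None = None) -> None:
    data = emit_config(model, settings, initial)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# run manifests

@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-exactly."""

    config: dict
    settings: dict
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    versions: dict[str, str] = field(default_factory=dict)


def write_manifest(path, model: ACMEModel, settings: SolverSettings,
                   outputs: dict[str, str], warnings: list[str] | None = None,
                   initial: dict | None = None) -> None:
    """Write the manifest atomically (temp file + rename)."""
    import scipy

    from . import __version__

    manifest = RunManifest(
        config=emit_config(model, initial=initial),
        settings=asdict(settings),
        outputs=dict(outputs),
        warnings=list(warnings or []),
        versions={"acmekit": __version__, "numpy": np.__version__, "scipy": scipy.__version__},
    )
    payload = asdict(manifest)
    payload["settings"]["snapshot_times"] = list(payload["settings"]["snapshot_times"])
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
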