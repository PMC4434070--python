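"""Run configuration: TOML/JSON schema, loading with full error reporting.

Schema (TOML shown; JSON mirrors it)::

    [model]
    family = "monod"          # monod | haldane | andrews | webb
    mu_max = 0.6              # 1/h
    k_s = 1.5                 # g/L
    # k_i = 30.0              # g/L, inhibited families only
    # beta = 0.4              # webb only
    gamma = 0.5               # g biomass / g substrate
    k1 = 0.0                  # 1/h, instantaneous decay
    k2 = 0.0                  # 1/h, delayed decay
    tau = 0.0                 # h, average lifetime

    [initial]
    s0 = 10.0                 # g/L
    history = "constant"      # constant | linear_ramp | exponential_ramp | tabular
    x0 = 0.1                  # g/L, biomass at t = 0
    # growth_fraction = 0.3   # ramps only
    # knots_t = [...]; knots_x = [...]   # tabular only

    [solver]
    horizon = 30.0            # h
    # h = 0.01                # optional fixed step
    # steps_per_delay = 64
    # interpolation = "cubic"

    [output]
    # dir = "."
    # stem = "run"

Unknown keys are rejected by name, and all schema violations are reported
together rather than first-only.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .dde import History, InitialData, ModelParameters, SolverOptions
from .errors import ValidationError
from .fixtures import Scenario
from .growth import Family, GrowthModelSpec

__all__ = ["RunConfig", "load_config", "dump_config", "scenario_to_config"]

_MODEL_KEYS = {"family", "mu_max", "k_s", "k_i", "beta", "gamma", "k1", "k2", "tau"}
_INITIAL_KEYS = {"s0", "history", "x0", "growth_fraction", "knots_t", "knots_x"}
_SOLVER_KEYS = {"horizon", "h", "steps_per_delay", "interpolation"}
_OUTPUT_KEYS = {"dir", "stem"}
_SECTIONS = {"model": _MODEL_KEYS, "initial": _INITIAL_KEYS, "solver": _SOLVER_KEYS,
             "output": _OUTPUT_KEYS}


@dataclass(frozen=True)
class RunConfig:
    """A fully-validated run: model, initial data, solver settings, output."""

    params: ModelParameters
    init: InitialData
    horizon: float
    solver: SolverOptions = field(default_factory=SolverOptions)
    output_dir: str = "."
    output_stem: str = "run"

    def to_dict(self) -> dict:
        g = self.params.growth
        model = {"family": g.family.value, "mu_max": g.mu_max, "k_s": g.k_s}
        if g.k_i is not None:
            model["k_i"] = g.k_i
        if g.beta is not None:
            model["beta"] = g.beta
        model.update(gamma=self.params.gamma, k1=self.params.k1, k2=self.params.k2,
                     tau=self.params.tau)
        hist = self.init.history
        if not isinstance(hist, History):
            raise ValidationError(["only named History objects can be serialized"])
        initial = {"s0": self.init.s0, "history": hist.kind}
        if hist.kind == "tabular":
            initial["knots_t"] = [t for t, _ in hist.knots]
            initial["knots_x"] = [x for _, x in hist.knots]
        else:
            initial["x0"] = hist.x0
            if hist.kind != "constant":
                initial["growth_fraction"] = hist.growth_fraction
        solver = {"horizon": self.horizon}
        if self.solver.h is not None:
            solver["h"] = self.solver.h
        if self.solver.steps_per_delay != 64:
            solver["steps_per_delay"] = self.solver.steps_per_delay
        if self.solver.interpolation != "cubic":
            solver["interpolation"] = self.solver.interpolation
        out = {}
        if self.output_dir != ".":
            out["dir"] = self.output_dir
        if self.output_stem != "run":
            out["stem"] = self.output_stem
        d = {"model": model, "initial": initial, "solver": solver}
        if out:
            d["output"] = out
        return d


def _check_keys(data: dict, problems: list):
    for section, keys in data.items():
        if section not in _SECTIONS:
            problems.append(f"unknown section [{section}]")
            continue
        if not isinstance(keys, dict):
            problems.append(f"section [{section}] must be a table/object")
            continue
        for k in keys:
            if k not in _SECTIONS[section]:
                problems.append(f"unknown key '{k}' in section [{section}]")
    for required in ("model", "initial", "solver"):
        if required not in data:
            problems.append(f"missing required section [{required}]")


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed TOML/JSON mapping.

    All violations — unknown keys, missing keys, invariant failures from the
    domain types — are collected and raised together in one
    :class:`ValidationError`.
    """
    problems: list = []
    _check_keys(data, problems)
    if problems:
        raise ValidationError(problems)

    model = data["model"]
    initial = data["initial"]
    solver = data["solver"]
    output = data.get("output", {})

    params = None
    spec = None
    try:
        spec = GrowthModelSpec(
            family=Family(model.get("family", "")),
            mu_max=model.get("mu_max", math.nan),
            k_s=model.get("k_s", math.nan),
            k_i=model.get("k_i"),
            beta=model.get("beta"),
        )
    except ValueError as exc:
        problems.extend(getattr(exc, "problems", [str(exc)]))
    try:
        params = ModelParameters(
            # fall back to a placeholder spec so the rate constants are still
            # checked (and reported) when the growth spec itself is invalid
            growth=spec if spec is not None else GrowthModelSpec("monod", 1.0, 1.0),
            gamma=model.get("gamma", math.nan),
            k1=model.get("k1", 0.0),
            k2=model.get("k2", 0.0),
            tau=model.get("tau", 0.0),
        )
    except ValueError as exc:
        problems.extend(getattr(exc, "problems", [str(exc)]))
    if spec is None:
        params = None

    init = None
    tau = params.tau if params is not None else model.get("tau", 0.0)
    try:
        kind = initial.get("history", "constant")
        if kind == "tabular":
            knots = tuple(zip(initial.get("knots_t", ()), initial.get("knots_x", ())))
            hist = History(kind="tabular", tau=tau, knots=knots)
        else:
            hist = History(
                kind=kind,
                x0=initial.get("x0"),
                tau=tau,
                growth_fraction=initial.get("growth_fraction", 0.0),
            )
        init = InitialData(s0=initial.get("s0", math.nan), history=hist)
    except ValueError as exc:
        problems.extend(getattr(exc, "problems", [str(exc)]))

    opts = None
    try:
        opts = SolverOptions(
            h=solver.get("h"),
            steps_per_delay=solver.get("steps_per_delay", 64),
            interpolation=solver.get("interpolation", "cubic"),
        )
    except ValueError as exc:
        problems.extend(getattr(exc, "problems", [str(exc)]))

    horizon = solver.get("horizon")
    if not (isinstance(horizon, (int, float)) and horizon > 0 and math.isfinite(horizon)):
        problems.append(f"solver.horizon must be a positive finite time, got {horizon}")

    if problems:
        raise ValidationError(problems)
    return RunConfig(
        params=params,
        init=init,
        horizon=float(horizon),
        solver=opts,
        output_dir=str(output.get("dir", ".")),
        output_stem=str(output.get("stem", "run")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML (default) or JSON run configuration."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return config_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return f"{v:.17g}" if v != int(v) or not math.isfinite(v) else f"{v:.1f}"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ValidationError([f"cannot serialize {type(v).__name__} to TOML"])


def dump_config(config: RunConfig, path) -> None:
    """Write a RunConfig as TOML (or JSON if the path ends in .json).

    Floats are written at 17 significant digits so that load/dump round-trips
    are lossless and byte-stable.
    """
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return
    lines = []
    for section, table in d.items():
        lines.append(f"[{section}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def scenario_to_config(scenario: Scenario) -> RunConfig:
    """Express a fixture scenario as an exportable run configuration."""
    return RunConfig(
        params=scenario.params,
        init=scenario.init,
        horizon=scenario.horizon,
        output_stem=scenario.name,
    )
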