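"""Run configuration: TOML files with CLI-overridable defaults.

Sections: ``[morphology]`` (source: swc/table path or generator spec),
``[biophysics]`` (BiophysParams overrides), ``[protocol]``
(StimulusProtocol fields), ``[solver]`` (method + precision), ``[output]``
(trace path).  Unknown keys are rejected by name; an empty file yields the
full defaults (dt 0.1 ms, amp0 -1 nA, damp 0.3 nA, serial solver, double
precision).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .mechanisms import BiophysParams
from .simulation import PRECISIONS, StimulusProtocol
from .solvers import SOLVERS


class ConfigError(ValueError):
    pass


_MORPH_KEYS = {"swc", "table", "fork_trunk", "fork_branch", "fork_total",
               "btree_depth", "cable", "mech"}
_SOLVER_KEYS = {"method", "precision", "warp"}
_OUTPUT_KEYS = {"traces", "seed"}


@dataclass
class RunConfig:
    """Fully resolved run description."""

    morphology: dict = field(default_factory=dict)
    biophys: BiophysParams = field(default_factory=BiophysParams)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    solver: str = "serial"
    precision: str = "double"
    warp: int = 32
    traces_out: str | None = None
    seed: int = 0


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(unknown)}; "
            f"allowed: {', '.join(sorted(allowed))}")


def _coerce(section: str, key: str, value, want: type):
    if want is float and isinstance(value, int):
        value = float(value)
    if not isinstance(value, want):
        raise ConfigError(
            f"[{section}] {key}: expected {want.__name__}, got {type(value).__name__}")
    return value


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML config file; ``None`` (or an empty file) gives defaults."""
    raw = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    _check_keys("top level", raw,
                {"morphology", "biophysics", "protocol", "solver", "output"})
    cfg = RunConfig()

    morph = raw.get("morphology", {})
    _check_keys("morphology", morph, _MORPH_KEYS)
    cfg.morphology = dict(morph)
    for key in ("swc", "table"):
        if key in morph and not Path(morph[key]).exists():
            raise ConfigError(f"[morphology] {key}: file not found: {morph[key]}")

    bio = raw.get("biophysics", {})
    bio_fields = {f.name: f for f in dataclasses.fields(BiophysParams)}
    _check_keys("biophysics", bio, set(bio_fields))
    cfg.biophys = BiophysParams(**{
        k: _coerce("biophysics", k, v, float) for k, v in bio.items()})

    proto = raw.get("protocol", {})
    proto_fields = {f.name for f in dataclasses.fields(StimulusProtocol)}
    _check_keys("protocol", proto, proto_fields)
    kwargs = {}
    for k, v in proto.items():
        want = int if k in ("n_sweeps", "stim_segment", "record_segment") else float
        kwargs[k] = _coerce("protocol", k, v, want)
    cfg.protocol = StimulusProtocol(**kwargs)

    slv = raw.get("solver", {})
    _check_keys("solver", slv, _SOLVER_KEYS)
    cfg.solver = _coerce("solver", "method", slv.get("method", cfg.solver), str)
    cfg.precision = _coerce("solver", "precision", slv.get("precision", cfg.precision), str)
    cfg.warp = _coerce("solver", "warp", slv.get("warp", cfg.warp), int)
    if cfg.solver not in SOLVERS:
        raise ConfigError(f"solver method {cfg.solver!r} not allowed; "
                          f"choose one of: {', '.join(SOLVERS)}")
    if cfg.precision not in PRECISIONS:
        raise ConfigError(f"precision {cfg.precision!r} not allowed; "
                          f"choose one of: {', '.join(PRECISIONS)}")

    out = raw.get("output", {})
    _check_keys("output", out, _OUTPUT_KEYS)
    if "traces" in out:
        cfg.traces_out = _coerce("output", "traces", out["traces"], str)
    if "seed" in out:
        cfg.seed = _coerce("output", "seed", out["seed"], int)
    return cfg
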