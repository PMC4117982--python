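"""Run configuration, serialization of results, logging, and test fixtures.

One plain-text (YAML) configuration format drives every protocol.  An
empty file resolves to the full default control configuration; unknown keys
are rejected by name so that typos cannot silently fall back to defaults.
Every result directory receives the fully resolved configuration as a
sidecar, which is sufficient to reproduce the result byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .channels import ChannelParams, DENSITY_PRESETS, RATE_PARAMS, RATE_PARAMS_TABULATED
from .engine import SimConfig, StimulusSpec, Trace
from .morphology import AxonSpec, DiscretizedCable, RegionSpec, build_axon, discretize
from . import morphology

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_results",
    "make_fixture",
    "setup_logging",
]

logger = logging.getLogger("axonwave")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(getattr(logging, level.upper()))


class ConfigError(ValueError):
    """A configuration file problem, naming the offending key."""


DEFAULTS: Dict[str, Any] = {
    "condition": "control",
    "protocol": "cv",
    "morphology": {
        "internode_length_um": 100.0,
        "n_nodes": 7,
        "affected_inrs": None,        # null = all internodes under AOE
        "ra_ohm_cm": 70.0,
        "lt_location": "JP",
        "aoe1_rescale": "area",
        "gna_scale": 1.0,
        "max_lambda_fraction": 0.1,
        "overrides": {},
    },
    "channels": {
        "preset": "equations",
        "gamma": 0.1,
        "rate_table": "default",      # or "tabulated" (literal, non-conducting)
        "g_na": None, "g_ht": None, "g_lt": None, "g_leak": None,
        "v_na": None, "v_ht": None, "v_lt": None, "v_leak": None,
    },
    "solver": {
        "dt_ms": 0.00125,
        "settle_ms": 50.0,
        "settle_dt_ms": 0.01,
        "t_stop_ms": 8.0,
        "v_init_mv": -63.0,
    },
    "stimulus": {
        "amplitude_na": 0.2,
        "onset_ms": 0.2,
        "duration_ms": 0.2,
        "node": 0,
    },
    "protocol_params": {
        "lengths_um": [50.0, 100.0, 150.0, 200.0, 250.0, 300.0],
        "amplitudes_na": [0.2, 0.4, 0.6, 0.8, 1.0],
        "pulse_ms": 200.0,
        "record_node": 3,
        "ks": None,
        "tolerance": 0.01,
        "escalate": True,
    },
    "log_level": "INFO",
}

_POSITIVE_KEYS = {
    ("solver", "dt_ms"),
    ("solver", "t_stop_ms"),
    ("morphology", "internode_length_um"),
    ("morphology", "max_lambda_fraction"),
    ("morphology", "ra_ohm_cm"),
    ("stimulus", "duration_ms"),
}


def _merge(defaults: Mapping[str, Any], given: Mapping[str, Any], path: str = "") -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for key, dval in defaults.items():
        here = f"{path}{key}"
        if key in given:
            gval = given[key]
            if isinstance(dval, dict) and not here.endswith("overrides"):
                if gval is None:
                    gval = {}
                if not isinstance(gval, dict):
                    raise ConfigError(f"'{here}' must be a mapping")
                out[key] = _merge(dval, gval, here + ".")
            else:
                out[key] = gval
        else:
            out[key] = {k: v for k, v in dval.items()} if isinstance(dval, dict) else dval
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration key '{path}{sorted(unknown)[0]}'")
    return out


@dataclass
class RunConfig:
    """A fully resolved run configuration."""

    data: Dict[str, Any] = field(default_factory=lambda: _merge(DEFAULTS, {}))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def channel_params(self) -> ChannelParams:
        ch = self.data["channels"]
        if ch["preset"] not in DENSITY_PRESETS:
            raise ConfigError(f"unknown channel preset '{ch['preset']}'")
        kw = dict(DENSITY_PRESETS[ch["preset"]])
        for name in ("g_na", "g_ht", "g_lt", "g_leak", "v_na", "v_ht", "v_lt", "v_leak"):
            if ch[name] is not None:
                kw[name] = float(ch[name])
        if ch["rate_table"] == "tabulated":
            kw["rate_table"] = RATE_PARAMS_TABULATED
        elif ch["rate_table"] != "default":
            raise ConfigError("channels.rate_table must be 'default' or 'tabulated'")
        try:
            return ChannelParams(gamma=float(ch["gamma"]), **kw)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def axon_spec(self) -> AxonSpec:
        m = self.data["morphology"]
        try:
            return build_axon(
                condition=self.data["condition"],
                internode_length_um=float(m["internode_length_um"]),
                n_nodes=int(m["n_nodes"]),
                affected_inrs=m["affected_inrs"],
                channel_params=self.channel_params(),
                lt_location=m["lt_location"],
                aoe1_rescale=m["aoe1_rescale"],
                gna_scale=float(m["gna_scale"]),
                ra_ohm_cm=float(m["ra_ohm_cm"]),
                overrides=m["overrides"] or None,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def cable(self) -> DiscretizedCable:
        return discretize(self.axon_spec(), float(self.data["morphology"]["max_lambda_fraction"]))

    def sim_config(self, with_stimulus: bool = True) -> SimConfig:
        s = self.data["solver"]
        stim = None
        if with_stimulus:
            st = self.data["stimulus"]
            stim = StimulusSpec(
                amplitude_na=float(st["amplitude_na"]),
                onset_ms=float(st["onset_ms"]),
                duration_ms=float(st["duration_ms"]),
                node=int(st["node"]),
            )
        try:
            return SimConfig(
                dt_ms=float(s["dt_ms"]),
                t_stop_ms=float(s["t_stop_ms"]),
                settle_ms=float(s["settle_ms"]),
                settle_dt_ms=None if s["settle_dt_ms"] is None else float(s["settle_dt_ms"]),
                v_init_mv=float(s["v_init_mv"]),
                stimulus=stim,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def _validate(data: Dict[str, Any]) -> None:
    for section, key in _POSITIVE_KEYS:
        val = data[section][key]
        if not (isinstance(val, (int, float)) and val > 0):
            raise ConfigError(f"'{section}.{key}' must be a positive number")
    if data["condition"] not in morphology.CONDITIONS:
        raise ConfigError(f"'condition' must be one of {morphology.CONDITIONS}")


def load_config(path: str | Path | None = None, overrides: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Load and resolve a configuration file (missing/empty file = defaults).

    ``overrides`` is a mapping of dotted keys (``"solver.dt_ms"``) applied
    after the file, mirroring the CLI ``--set`` option.
    """
    given: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        given = loaded
    data = _merge(DEFAULTS, given)
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        node = data
        for p in parts[:-1]:
            if p not in node:
                raise ConfigError(f"unknown configuration key '{dotted}'")
            node = node[p]
        if parts[-1] not in node:
            raise ConfigError(f"unknown configuration key '{dotted}'")
        node[parts[-1]] = value
    _validate(data)
    cfg = RunConfig(data)
    cfg.sim_config()      # surface range errors early, naming the key
    cfg.channel_params()
    return cfg


def trace_frame(trace: Trace) -> pd.DataFrame:
    """Tidy table: time column plus one potential column per node."""
    cols = {"t_ms": trace.t_ms}
    for j, node in enumerate(trace.sites):
        cols[f"v_node{int(node)}_mv"] = trace.v_mv[:, j]
    for name, arr in trace.currents_na.items():
        for j, node in enumerate(trace.sites):
            cols[f"i_{name}_node{int(node)}_na"] = arr[:, j]
    return pd.DataFrame(cols)


def write_results(
    result: Any,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    name: str = "result",
) -> List[Path]:
    """Write a protocol result as CSV plus a resolved-config sidecar.

    Accepts a Trace, a SweepResult, a DataFrame, or a mapping of such
    objects (one file per entry).  File contents carry no timestamps, so
    identical runs produce byte-identical files.
    """
    from .protocols import SweepResult  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(obj: Any, stem: str) -> None:
        if isinstance(obj, Trace):
            frame = trace_frame(obj)
        elif isinstance(obj, SweepResult):
            frame = pd.DataFrame(obj.to_records())
        elif isinstance(obj, pd.DataFrame):
            frame = obj
        elif isinstance(obj, Mapping):
            for key, sub in obj.items():
                emit(sub, f"{stem}_{key}")
            return
        else:
            raise TypeError(f"cannot serialize result of type {type(obj).__name__}")
        path = out / f"{stem}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    emit(result, name)
    if config is not None:
        sidecar = out / f"{name}_config.yaml"
        sidecar.write_text(config.to_yaml())
        written.append(sidecar)
    for p in written:
        logger.info("wrote %s", p)
    return written


FIXTURES = ("single-node", "passive-uniform", "mini-3node")


def make_fixture(name: str) -> AxonSpec:
    """Miniature axon specifications used across the test suite.

    * ``single-node`` — one isolated nodal compartment with the full
      channel set (the ODE-oracle geometry).
    * ``passive-uniform`` — a 6 mm uniform unmyelinated cylinder with leak
      only (closed-form cable tests; long against its ~0.4 mm length
      constant so interior decay is end-effect free).
    * ``mini-3node`` — 3 nodes / 2 internodes of control geometry.
    """
    params = ChannelParams()
    if name == "single-node":
        node = RegionSpec("node", 1.3, 0.8, 1.0, params.g_leak,
                          {"na": params.g_na, "ht": params.g_ht})
        return AxonSpec("control", (node,), 1, 0.0, 70.0, frozenset(), params)
    if name == "passive-uniform":
        passive = ChannelParams(g_na=0.0, g_ht=0.0, g_lt=0.0)
        seg = RegionSpec("node", 6000.0, 1.0, 1.0, passive.g_leak, {})
        return AxonSpec("control", (seg,), 1, 0.0, 70.0, frozenset(), passive)
    if name == "mini-3node":
        return build_axon("control", n_nodes=3)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
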