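"""Voltage-gated and leak membrane currents of the auditory-nerve axon model.

The model carries four membrane currents:

* ``I_Na``  — fast sodium current, ``g_Na * m^3 * h * (V - V_Na)``, nodal.
* ``I_HT``  — high-threshold (Kv3.1-type) potassium current,
  ``g_HT * n^3 * (1 - gamma + gamma*p) * (V - V_HT)``, nodal.
* ``I_LT``  — low-threshold (Kv1.1-type) potassium current,
  ``g_LT * l * r * (V - V_LT)``, juxtaparanodal.
* ``I_L``   — ohmic leak, ``g_L * (V - V_L)``, everywhere.

Each gating variable ``j`` obeys first-order Hodgkin–Huxley kinetics

    dj/dt = alpha_j(V) * (1 - j) - beta_j(V) * j

with purely exponential rate laws ``alpha = k_a * exp(eta_a * V)`` and
``beta = k_b * exp(eta_b * V)`` (``V`` in mV, rates in 1/ms).

Units: conductance densities in mS/cm^2, potentials in mV, time in ms,
current densities returned in mA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "GATE_NAMES",
    "GatingRateParams",
    "ChannelParams",
    "GatingState",
    "RATE_PARAMS",
    "DENSITY_PRESETS",
    "rate_constants",
    "gate_steady_state",
    "gate_derivative",
    "gate_exponential_update",
    "ionic_current_density",
]

GATE_NAMES: Tuple[str, ...] = ("m", "h", "n", "p", "l", "r")


@dataclass(frozen=True)
class GatingRateParams:
    """Exponential rate-law constants for one gating variable.

    ``k_alpha``/``k_beta`` are the forward/backward rates at 0 mV (1/ms);
    ``eta_alpha``/``eta_beta`` their voltage sensitivities (1/mV).
    """

    gate_name: str
    k_alpha: float
    eta_alpha: float
    k_beta: float
    eta_beta: float

    def __post_init__(self) -> None:
        if self.gate_name not in GATE_NAMES:
            raise ValueError(f"unknown gate name {self.gate_name!r}")
        if not (self.k_alpha > 0 and self.k_beta > 0):
            raise ValueError("rate constants k_alpha, k_beta must be positive")


#: Rate-law constants for the six gates (k in 1/ms at 0 mV, eta in 1/mV),
#: exactly as tabulated in the data set this model derives from.  Under
#: this table the sodium activation midpoint sits near -95 mV: m is almost
#: fully open at rest, the axon settles at a depolarized potential with
#: h ~ 0.04, and no action potential can be evoked or conducted.
RATE_PARAMS_TABULATED: Dict[str, GatingRateParams] = {
    "m": GatingRateParams("m", 76.4, 0.037, 0.0381, -0.043),
    "h": GatingRateParams("h", 0.00013, -0.1216, 1.999, 0.0384),
    "n": GatingRateParams("n", 0.2719, 0.04, 0.1974, 0.0),
    "p": GatingRateParams("p", 0.00713, -0.1942, 0.0935, 0.0058),
    "l": GatingRateParams("l", 1.2, 0.03512, 0.2248, -0.0319),
    "r": GatingRateParams("r", 0.0438, -0.0053, 0.0562, -0.0047),
}

#: Default rate table.  Identical to the tabulated set except that the
#: m-gate backward rate reads 3.81 /ms instead of 0.0381 /ms: the package
#: treats the tabulated figure as a decimal transcription error, since the
#: corrected value places the Na activation midpoint at -37.5 mV
#: (tau_m ~ 0.03 ms), gives a resting potential of about -68.5 mV, and
#: yields a conducting, excitable axon, whereas the literal value yields a
#: non-excitable one.  Pass ``RATE_PARAMS_TABULATED`` through
#: ``ChannelParams(rate_table=...)`` to simulate the literal variant.
RATE_PARAMS: Dict[str, GatingRateParams] = {
    **RATE_PARAMS_TABULATED,
    "m": GatingRateParams("m", 76.4, 0.037, 3.81, -0.043),
}

#: Alternative maximal-conductance sets (mS/cm^2).  "equations" is the
#: default; "capacitance-derived" is the set quoted per unit cell
#: capacitance in the morphology description.
DENSITY_PRESETS: Dict[str, Dict[str, float]] = {
    "equations": {"g_na": 50.0, "g_ht": 15.0, "g_lt": 2.0},
    "capacitance-derived": {"g_na": 6.6, "g_ht": 1.98, "g_lt": 2.13},
}


@dataclass(frozen=True)
class ChannelParams:
    """Maximal conductance densities, reversal potentials and I_HT mixing.

    ``gamma`` weights the slow activation gate ``p`` inside I_HT via the
    factor ``(1 - gamma + gamma*p)``; it is not assigned a value by the
    source model and defaults to 0.1.  ``lt_exponents`` are the powers of
    the ``l`` and ``r`` gates in I_LT (first power each by default).
    """

    g_na: float = 50.0      # mS/cm^2
    g_ht: float = 15.0      # mS/cm^2
    g_lt: float = 2.0       # mS/cm^2
    g_leak: float = 0.2     # mS/cm^2 (nodal / bare membrane)
    v_na: float = 50.0      # mV
    v_ht: float = -80.0     # mV
    v_lt: float = -80.0     # mV
    v_leak: float = -63.0   # mV
    gamma: float = 0.1
    lt_exponents: Tuple[int, int] = (1, 1)
    rate_table: Optional[Mapping[str, GatingRateParams]] = None

    def rates(self) -> Mapping[str, GatingRateParams]:
        """The gating rate table in force (default table when unset)."""
        return self.rate_table if self.rate_table is not None else RATE_PARAMS

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        for name in ("g_na", "g_ht", "g_lt", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("v_na", "v_ht", "v_lt", "v_leak"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_preset(self, preset: str) -> "ChannelParams":
        """Return a copy using a named conductance-density preset."""
        try:
            densities = DENSITY_PRESETS[preset]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(DENSITY_PRESETS)}"
            ) from None
        return replace(self, **densities)


@dataclass
class GatingState:
    """The six gating variables; scalars or arrays over compartments."""

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    p: np.ndarray
    l: np.ndarray
    r: np.ndarray

    @classmethod
    def steady(cls, v, params: Mapping[str, GatingRateParams] = RATE_PARAMS) -> "GatingState":
        """All gates at their voltage-dependent steady state for ``v``."""
        vals = {}
        for g in GATE_NAMES:
            inf, _ = gate_steady_state(params[g], v)
            vals[g] = np.asarray(inf, dtype=float)
        return cls(**vals)

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {g: getattr(self, g) for g in GATE_NAMES}

    def copy(self) -> "GatingState":
        return GatingState(**{g: np.array(getattr(self, g), copy=True) for g in GATE_NAMES})


def _check_finite_v(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    return v


def rate_constants(gate: GatingRateParams, v):
    """Forward and backward rates (1/ms) at membrane potential ``v`` (mV).

    ``alpha = k_alpha * exp(eta_alpha * v)``, ``beta = k_beta * exp(eta_beta * v)``.
    """
    v = _check_finite_v(v)
    alpha = gate.k_alpha * np.exp(gate.eta_alpha * v)
    beta = gate.k_beta * np.exp(gate.eta_beta * v)
    return alpha, beta


def gate_steady_state(gate: GatingRateParams, v):
    """Equilibrium value ``j_inf = a/(a+b)`` and time constant ``tau = 1/(a+b)``."""
    alpha, beta = rate_constants(gate, v)
    total = alpha + beta
    return alpha / total, 1.0 / total


def gate_derivative(j, v, gate: GatingRateParams):
    """dj/dt (1/ms) for gate value ``j`` at potential ``v``."""
    j = np.asarray(j, dtype=float)
    if np.any(j < 0.0) or np.any(j > 1.0):
        raise ValueError("gate value outside [0, 1]")
    alpha, beta = rate_constants(gate, v)
    return alpha * (1.0 - j) - beta * j


def gate_exponential_update(j, v, gate: GatingRateParams, dt: float):
    """Advance ``j`` by ``dt`` with rates frozen at ``v`` (exact for frozen rates).

    ``j(t+dt) = j_inf + (j - j_inf) * exp(-dt/tau)``.  Maps [0,1] into
    itself for any dt > 0, which keeps the staggered integration scheme
    unconditionally stable in the gates.
    """
    inf, tau = gate_steady_state(gate, v)
    return inf + (np.asarray(j, dtype=float) - inf) * np.exp(-dt / tau)


def ionic_current_density(
    state: GatingState,
    v,
    params: ChannelParams,
    region_channels: Mapping[str, float] | None = None,
):
    """Per-current membrane current densities (mA/cm^2) and their sum.

    ``region_channels`` maps current names (``"na"``, ``"ht"``, ``"lt"``,
    ``"leak"``) to conductance densities in mS/cm^2 for the local patch of
    membrane; currents absent from the map contribute exactly zero.  When
    omitted, the densities in ``params`` are used for all four currents.

    Outward current is positive.
    """
    v = _check_finite_v(v)
    if region_channels is None:
        region_channels = {
            "na": params.g_na,
            "ht": params.g_ht,
            "lt": params.g_lt,
            "leak": params.g_leak,
        }
    zeros = np.zeros_like(v)
    out: Dict[str, np.ndarray] = {}

    g = region_channels.get("na", 0.0)
    out["na"] = 1e-3 * g * state.m**3 * state.h * (v - params.v_na) if g else zeros.copy()

    g = region_channels.get("ht", 0.0)
    if g:
        mix = 1.0 - params.gamma + params.gamma * state.p
        out["ht"] = 1e-3 * g * state.n**3 * mix * (v - params.v_ht)
    else:
        out["ht"] = zeros.copy()

    g = region_channels.get("lt", 0.0)
    if g:
        el, er = params.lt_exponents
        out["lt"] = 1e-3 * g * state.l**el * state.r**er * (v - params.v_lt)
    else:
        out["lt"] = zeros.copy()

    g = region_channels.get("leak", 0.0)
    out["leak"] = 1e-3 * g * (v - params.v_leak) if g else zeros.copy()

    out["total"] = out["na"] + out["ht"] + out["lt"] + out["leak"]
    return out
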