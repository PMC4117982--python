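"""Periodic axon geometry and its compartmental discretization.

The central auditory-nerve axon is modelled as seven nodes of Ranvier
alternating with six 100-um myelinated internodal regions (INR).  Each INR
is subdivided symmetrically into paranode (PN), juxtaparanode (JP) and a
central internodal axon stretch:

    node | PN JP axon JP PN | node | ...

Acoustic overexposure (AOE) remodels these subdomains.  Two scenarios are
built from the measured post-exposure geometry:

* ``AOE1`` — the channels of each subdomain spread evenly over its new
  dimensions: every region takes its AOE geometry, and channel densities
  are rescaled so that the total number of channels per region is
  conserved.
* ``AOE2`` — channels stay where they were: the node keeps its original
  length (at the enlarged diameter) and is flanked by passive bare-membrane
  inserts ``n1``; the JP keeps its original extent and passive myelinated
  inserts ``j1`` absorb its elongation.

Myelinated membrane is represented as a single effective cable (myelin
lamellae folded into the lumped specific capacitance and leak of the
internodal regions); extracellular resistance is zero and both cable ends
are sealed.

Units: lengths and diameters in um, specific capacitance in uF/cm^2,
conductance densities in mS/cm^2, axoplasmic resistivity in Ohm*cm.  The
discretized cable carries absolute quantities in nF, uS and MOhm so that
uS*mV = nA and nF*mV/ms = nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .channels import ChannelParams

__all__ = [
    "CONDITIONS",
    "REGION_KINDS",
    "RegionSpec",
    "AxonSpec",
    "DiscretizedCable",
    "surface_area",
    "length_constant",
    "aoe1_channel_rescaling",
    "build_axon",
    "discretize",
]

CONDITIONS = ("control", "AOE1", "AOE2")
REGION_KINDS = ("node", "n1", "PN", "JP", "j1", "axon")

# Region geometry per condition: kind -> (length um, diameter um).
GEOMETRY: Dict[str, Dict[str, Tuple[float, float]]] = {
    "control": {
        "node": (1.3, 0.8),
        "PN": (2.34, 0.75),
        "JP": (5.14, 2.13),
        "axon": (10.46, 1.25),
    },
    "AOE1": {
        "node": (6.15, 1.28),
        "PN": (1.52, 1.23),
        "JP": (6.23, 1.32),
        "axon": (9.79, 1.25),
    },
    "AOE2": {
        "node": (1.3, 1.28),
        "n1": (2.425, 1.28),
        "PN": (2.34, 1.23),
        "JP": (5.14, 2.13),
        "j1": (1.09, 1.16),
        "axon": (9.79, 1.25),
    },
}

# Passive membrane of myelinated internodal regions (PN/JP/axon, and j1),
# with the myelin sheath lumped into the effective values.
INTERNODAL_PASSIVE = {
    "control": {"cm_specific": 0.0184, "g_leak": 0.01089},  # uF/cm^2, mS/cm^2
    "AOE": {"cm_specific": 0.0290, "g_leak": 0.0203},
}
# Bare (unmyelinated) membrane: nodes and the n1 nodal-gap inserts.
BARE_PASSIVE = {"cm_specific": 1.0, "g_leak": 0.2}

RA_DEFAULT = 70.0  # Ohm*cm, axoplasmic resistivity, uniform


@dataclass(frozen=True)
class RegionSpec:
    """One anatomical region: geometry, passive membrane, channel content."""

    kind: str
    length_um: float
    diameter_um: float
    cm_specific: float                      # uF/cm^2
    g_leak: float                           # mS/cm^2
    channel_densities: Mapping[str, float] = field(default_factory=dict)  # mS/cm^2

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError(f"{self.kind}: length and diameter must be positive")
        if self.cm_specific <= 0:
            raise ValueError(f"{self.kind}: cm_specific must be positive")
        if self.kind in ("n1", "j1") and self.channel_densities:
            raise ValueError(f"{self.kind} regions carry no voltage-dependent channels")
        object.__setattr__(self, "channel_densities", dict(self.channel_densities))

    @property
    def area_um2(self) -> float:
        return surface_area(self.length_um, self.diameter_um)[0]

    @property
    def area_cm2(self) -> float:
        return surface_area(self.length_um, self.diameter_um)[1]


@dataclass(frozen=True)
class AxonSpec:
    """An ordered node/internode chain ready for discretization."""

    condition: str
    regions: Tuple[RegionSpec, ...]
    n_nodes: int
    internode_length_um: float
    ra_ohm_cm: float
    affected_inrs: FrozenSet[int]
    channel_params: ChannelParams

    def __post_init__(self) -> None:
        if self.regions[0].kind != "node" or self.regions[-1].kind != "node":
            raise ValueError("region chain must begin and end with a node")


def surface_area(length_um: float, diameter_um: float) -> Tuple[float, float]:
    """Cylindrical lateral surface area, returned as (um^2, cm^2)."""
    if length_um < 0 or diameter_um < 0:
        raise ValueError("length and diameter must be non-negative")
    a_um2 = math.pi * diameter_um * length_um
    return a_um2, a_um2 * 1e-8


def length_constant(radius_cm: float, r_m: float, r_a: float) -> float:
    """Passive length constant lambda = sqrt(radius * R_m / (2 * R_a)) in cm.

    ``radius_cm`` is the axon radius (cm), ``r_m`` the specific membrane
    resistance (Ohm*cm^2) and ``r_a`` the axoplasmic resistivity (Ohm*cm).
    """
    if radius_cm <= 0 or r_m <= 0 or r_a <= 0:
        raise ValueError("length-constant inputs must be positive")
    return math.sqrt(radius_cm * r_m / (2.0 * r_a))


def region_lambda_um(region: RegionSpec, ra_ohm_cm: float) -> float:
    """Local length constant (um) using the region's effective leak."""
    radius_cm = 0.5 * region.diameter_um * 1e-4
    r_m = 1.0 / (region.g_leak * 1e-3)  # Ohm*cm^2
    return length_constant(radius_cm, r_m, ra_ohm_cm) * 1e4


def aoe1_channel_rescaling(
    control_region: RegionSpec, aoe_region: RegionSpec, mode: str = "area"
) -> float:
    """Density scale factor that conserves channel number after remodeling.

    ``mode="area"`` (default) conserves total conductance: the factor is the
    ratio of control to remodeled surface area, so density*area is exactly
    preserved.  ``mode="length"`` rescales by the length ratio only.
    """
    if control_region.kind != aoe_region.kind:
        raise ValueError(
            f"region kinds differ: {control_region.kind!r} vs {aoe_region.kind!r}"
        )
    if mode == "area":
        return control_region.area_um2 / aoe_region.area_um2
    if mode == "length":
        return control_region.length_um / aoe_region.length_um
    raise ValueError(f"unknown rescaling mode {mode!r}")


def _geom(condition: str, kind: str, overrides: Mapping | None) -> Tuple[float, float]:
    l, d = GEOMETRY[condition][kind]
    if overrides and kind in overrides:
        o = overrides[kind]
        l = float(o.get("length_um", l))
        d = float(o.get("diameter_um", d))
    return l, d


def _region(
    condition: str,
    kind: str,
    passive: Mapping[str, float],
    densities: Mapping[str, float],
    overrides: Mapping | None,
    length_um: float | None = None,
) -> RegionSpec:
    l, d = _geom(condition, kind, overrides)
    if length_um is not None:
        l = length_um
    return RegionSpec(
        kind=kind,
        length_um=l,
        diameter_um=d,
        cm_specific=passive["cm_specific"],
        g_leak=passive["g_leak"],
        channel_densities=densities,
    )


def build_axon(
    condition: str = "control",
    internode_length_um: float = 100.0,
    n_nodes: int = 7,
    affected_inrs: Optional[Iterable[int]] = None,
    channel_params: Optional[ChannelParams] = None,
    lt_location: str = "JP",
    aoe1_rescale: str = "area",
    gna_scale: float = 1.0,
    ra_ohm_cm: float = RA_DEFAULT,
    overrides: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> AxonSpec:
    """Assemble the region chain for a condition.

    ``affected_inrs`` selects which internodes (0-based, internode ``i``
    lies between nodes ``i`` and ``i+1``) carry the AOE remodeling; by
    default all of them do under AOE1/AOE2 and none under control.  A node
    takes AOE geometry when at least one adjacent internode is affected.
    The central ``axon`` region of every internode is stretched so that the
    internode's total length equals ``internode_length_um`` (the tabulated
    axon length is nominal).  ``gna_scale`` multiplies the nodal sodium
    density uniformly (used by the conduction-block protocols).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if gna_scale < 0:
        raise ValueError("gna_scale must be non-negative")
    if lt_location not in ("JP", "PN"):
        raise ValueError("lt_location must be 'JP' or 'PN'")
    params = channel_params or ChannelParams()
    n_inr = n_nodes - 1
    if affected_inrs is None:
        affected = frozenset(range(n_inr)) if condition != "control" else frozenset()
    else:
        affected = frozenset(int(i) for i in affected_inrs)
        if any(i < 0 or i >= n_inr for i in affected):
            raise ValueError("affected internode index out of range")
        if condition == "control" and affected:
            raise ValueError("control condition admits no affected internodes")

    # Voltage-gated channel densities per region kind, control condition.
    # (Leak lives in each region's g_leak field, not in the density map.)
    node_ctrl = {"na": params.g_na * gna_scale, "ht": params.g_ht}
    pn_ctrl: Dict[str, float] = {}
    jp_ctrl: Dict[str, float] = {}
    (jp_ctrl if lt_location == "JP" else pn_ctrl)["lt"] = params.g_lt

    ctrl_regions = {
        k: RegionSpec(k, *GEOMETRY["control"][k],
                      **(BARE_PASSIVE if k == "node" else INTERNODAL_PASSIVE["control"]),
                      channel_densities={})
        for k in ("node", "PN", "JP")
    }

    def aoe_densities(kind: str, base: Dict[str, float]) -> Dict[str, float]:
        """Channel densities for an AOE-remodeled region of ``kind``."""
        if condition == "AOE2":
            return dict(base)  # densities unchanged; geometry handles the rest
        aoe_geom = RegionSpec(kind, *GEOMETRY["AOE1"][kind],
                              **(BARE_PASSIVE if kind == "node"
                                 else INTERNODAL_PASSIVE["AOE"]),
                              channel_densities={})
        f = aoe1_channel_rescaling(ctrl_regions[kind], aoe_geom, mode=aoe1_rescale)
        return {name: g * f for name, g in base.items()}

    def node_region(i: int) -> RegionSpec:
        is_aoe = condition != "control" and (
            (i - 1) in affected or i in affected
        )
        if not is_aoe:
            return _region("control", "node", BARE_PASSIVE, node_ctrl, overrides)
        return _region(condition, "node", BARE_PASSIVE,
                       aoe_densities("node", node_ctrl), overrides)

    def internode(i: int) -> List[RegionSpec]:
        is_aoe = i in affected
        cond = condition if is_aoe else "control"
        passive = INTERNODAL_PASSIVE["AOE" if is_aoe else "control"]
        pn_d = aoe_densities("PN", pn_ctrl) if is_aoe else pn_ctrl
        jp_d = aoe_densities("JP", jp_ctrl) if is_aoe else jp_ctrl
        pn = _region(cond, "PN", passive, pn_d, overrides)
        jp = _region(cond, "JP", passive, jp_d, overrides)
        flank: List[RegionSpec] = [pn, jp]
        if cond == "AOE2":
            n1 = _region(cond, "n1", BARE_PASSIVE, {}, overrides)
            j1 = _region(cond, "j1", passive, {}, overrides)
            flank = [n1, pn, jp, j1]
        fixed = 2.0 * sum(reg.length_um for reg in flank)
        axon_len = internode_length_um - fixed
        if axon_len <= 0:
            raise ValueError(
                f"internode_length_um={internode_length_um} too short for the "
                f"{fixed:.2f} um of fixed PN/JP (and insert) regions"
            )
        ax = _region(cond, "axon", passive, {}, overrides, length_um=axon_len)
        return flank + [ax] + flank[::-1]

    chain: List[RegionSpec] = [node_region(0)]
    for i in range(n_inr):
        chain.extend(internode(i))
        chain.append(node_region(i + 1))

    return AxonSpec(
        condition=condition,
        regions=tuple(chain),
        n_nodes=n_nodes,
        internode_length_um=internode_length_um,
        ra_ohm_cm=ra_ohm_cm,
        affected_inrs=affected,
        channel_params=params,
    )


@dataclass
class DiscretizedCable:
    """Solver-ready chain of isopotential compartments.

    All arrays have one entry per compartment except ``r_axial_mohm``
    (one per adjacent pair).  ``node_center_idx[i]`` is the compartment
    index of node ``i``'s center, the recording/stimulation sites.
    """

    kind: np.ndarray               # region kind per compartment (str)
    length_um: np.ndarray
    diameter_um: np.ndarray
    x_center_um: np.ndarray        # center position from the proximal end
    area_cm2: np.ndarray
    c_nf: np.ndarray               # absolute capacitance, nF
    g_leak_us: np.ndarray          # absolute leak conductance, uS
    g_na_us: np.ndarray
    g_ht_us: np.ndarray
    g_lt_us: np.ndarray
    r_axial_mohm: np.ndarray       # between compartment i and i+1
    node_center_idx: np.ndarray
    params: ChannelParams
    spec: AxonSpec

    @property
    def n_comp(self) -> int:
        return self.kind.size

    def equals(self, other: "DiscretizedCable") -> bool:
        num = ("length_um", "diameter_um", "x_center_um", "area_cm2", "c_nf",
               "g_leak_us", "g_na_us", "g_ht_us", "g_lt_us", "r_axial_mohm",
               "node_center_idx")
        return (
            np.array_equal(self.kind, other.kind)
            and all(np.array_equal(getattr(self, a), getattr(other, a)) for a in num)
            and self.params == other.params
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per compartment (the `describe` CLI table)."""
        r_next = np.append(self.r_axial_mohm, np.nan)
        return pd.DataFrame(
            {
                "index": np.arange(self.n_comp),
                "kind": self.kind,
                "x_center_um": self.x_center_um,
                "length_um": self.length_um,
                "diameter_um": self.diameter_um,
                "area_cm2": self.area_cm2,
                "c_nF": self.c_nf,
                "g_leak_uS": self.g_leak_us,
                "g_na_uS": self.g_na_us,
                "g_ht_uS": self.g_ht_us,
                "g_lt_uS": self.g_lt_us,
                "r_axial_to_next_MOhm": r_next,
            }
        )


def _half_axial_mohm(length_um: float, diameter_um: float, ra_ohm_cm: float) -> float:
    """Axial resistance of half a compartment, 4*Ra*(l/2)/(pi*d^2), in MOhm."""
    l_cm = length_um * 1e-4
    d_cm = diameter_um * 1e-4
    return 4.0 * ra_ohm_cm * (l_cm / 2.0) / (math.pi * d_cm**2) / 1e6


def discretize(spec: AxonSpec, max_lambda_fraction: float = 0.1) -> DiscretizedCable:
    """Split every region into compartments no longer than 0.1*lambda.

    Each region is divided into equal sub-compartments; the count is the
    smallest that brings the sub-length below ``max_lambda_fraction`` times
    the region's local length constant, so short regions stay a single
    compartment and total length is conserved exactly.
    """
    if max_lambda_fraction <= 0:
        raise ValueError("max_lambda_fraction must be positive")
    kinds: List[str] = []
    lengths: List[float] = []
    diams: List[float] = []
    cms: List[float] = []
    gleaks: List[float] = []
    dens: List[Mapping[str, float]] = []
    node_centers: List[int] = []

    for region in spec.regions:
        lam = region_lambda_um(region, spec.ra_ohm_cm)
        n = max(1, math.ceil(region.length_um / (max_lambda_fraction * lam) - 1e-12))
        sub = region.length_um / n
        start = len(kinds)
        for _ in range(n):
            kinds.append(region.kind)
            lengths.append(sub)
            diams.append(region.diameter_um)
            cms.append(region.cm_specific)
            gleaks.append(region.g_leak)
            dens.append(region.channel_densities)
        if region.kind == "node":
            node_centers.append(start + n // 2)

    length_um = np.asarray(lengths)
    diameter_um = np.asarray(diams)
    area_cm2 = math.pi * diameter_um * length_um * 1e-8
    c_nf = area_cm2 * np.asarray(cms) * 1e3          # uF/cm^2 * cm^2 -> uF -> nF
    g_leak_us = area_cm2 * np.asarray(gleaks) * 1e3  # mS/cm^2 * cm^2 -> mS -> uS

    def chan(name: str) -> np.ndarray:
        return area_cm2 * np.array([d.get(name, 0.0) for d in dens]) * 1e3

    half = np.array(
        [_half_axial_mohm(l, d, spec.ra_ohm_cm) for l, d in zip(lengths, diams)]
    )
    r_axial = half[:-1] + half[1:]
    x_center = np.cumsum(length_um) - 0.5 * length_um

    return DiscretizedCable(
        kind=np.asarray(kinds, dtype=object),
        length_um=length_um,
        diameter_um=diameter_um,
        x_center_um=x_center,
        area_cm2=area_cm2,
        c_nf=c_nf,
        g_leak_us=g_leak_us,
        g_na_us=chan("na"),
        g_ht_us=chan("ht"),
        g_lt_us=chan("lt"),
        r_axial_mohm=r_axial,
        node_center_idx=np.asarray(node_centers, dtype=int),
        params=spec.channel_params,
        spec=spec,
    )
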