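"""Axon geometry, dysmyelination variants, and discretization."""

import math

import numpy as np
import pytest

from axonwave.channels import ChannelParams
from axonwave.morphology import (
    AxonSpec,
    GEOMETRY,
    RegionSpec,
    aoe1_channel_rescaling,
    build_axon,
    discretize,
    length_constant,
    region_lambda_um,
    surface_area,
)


def nodal_capacitance_pf(length_um, diameter_um, cm_uf_per_cm2=1.0):
    _, a_cm2 = surface_area(length_um, diameter_um)
    return a_cm2 * cm_uf_per_cm2 * 1e6  # uF -> pF


def test_surface_area_and_nodal_capacitance():
    a_um2, a_cm2 = surface_area(1.3, 0.8)
    assert a_um2 == pytest.approx(math.pi * 0.8 * 1.3, rel=1e-15)
    assert a_cm2 == pytest.approx(a_um2 * 1e-8, rel=1e-15)
    assert nodal_capacitance_pf(1.3, 0.8) == pytest.approx(0.0327, abs=5e-5)
    assert nodal_capacitance_pf(6.15, 1.28) == pytest.approx(0.247, abs=5e-4)
    assert surface_area(0.0, 1.0)[0] == 0.0


def test_length_constant_scaling():
    base = length_constant(1e-4, 5000.0, 70.0)
    assert length_constant(4e-4, 5000.0, 70.0) == pytest.approx(2 * base, rel=1e-12)
    assert length_constant(1e-4, 5000.0 / 4, 70.0 / 4) == pytest.approx(base, rel=1e-12)
    with pytest.raises(ValueError):
        length_constant(-1.0, 5000.0, 70.0)


def test_internodal_axon_length_constant_regression():
    spec = build_axon("control")
    axon = next(r for r in spec.regions if r.kind == "axon")
    assert region_lambda_um(axon, 70.0) == pytest.approx(2024.7063781244271, rel=1e-12)


def test_control_geometry_matches_measured_dimensions():
    spec = build_axon("control")
    dims = {r.kind: (r.length_um, r.diameter_um) for r in spec.regions if r.kind != "axon"}
    assert dims["node"] == (1.3, 0.8)
    assert dims["PN"] == (2.34, 0.75)
    assert dims["JP"] == (5.14, 2.13)
    axon = next(r for r in spec.regions if r.kind == "axon")
    assert axon.diameter_um == 1.25
    # the central stretch fills the internode to the configured length
    assert axon.length_um == pytest.approx(100.0 - 2 * (2.34 + 5.14), rel=1e-12)
    kinds = [r.kind for r in spec.regions]
    assert kinds[0] == kinds[-1] == "node"
    assert kinds[1:6] == ["PN", "JP", "axon", "JP", "PN"]


def test_aoe2_insert_regions_reconstruct_aoe1_totals():
    """Node + two n1 flanks = elongated AOE node; JP + j1 = elongated JP."""
    g = GEOMETRY
    assert g["AOE2"]["node"][0] + 2 * g["AOE2"]["n1"][0] == pytest.approx(
        g["AOE1"]["node"][0], rel=1e-12)  # 1.3 + 2*2.425 = 6.15
    assert g["AOE2"]["JP"][0] + g["AOE2"]["j1"][0] == pytest.approx(
        g["AOE1"]["JP"][0], rel=1e-12)  # 5.14 + 1.09 = 6.23
    spec = build_axon("AOE2")
    kinds = [r.kind for r in spec.regions[:10]]
    assert kinds == ["node", "n1", "PN", "JP", "j1", "axon", "j1", "JP", "PN", "n1"]
    n1 = next(r for r in spec.regions if r.kind == "n1")
    assert not n1.channel_densities
    assert n1.cm_specific == 1.0 and n1.g_leak == 0.2  # bare membrane


def test_aoe1_rescaling_factor_and_conservation():
    ctrl = RegionSpec("node", 1.3, 0.8, 1.0, 0.2, {})
    aoe = RegionSpec("node", 6.15, 1.28, 1.0, 0.2, {})
    f = aoe1_channel_rescaling(ctrl, aoe)
    assert f == pytest.approx((0.8 * 1.3) / (1.28 * 6.15), rel=1e-12)
    assert f == pytest.approx(0.132, abs=5e-4)
    assert aoe1_channel_rescaling(ctrl, ctrl) == 1.0
    # density * area conserved to machine precision
    assert 50.0 * f * aoe.area_um2 == pytest.approx(50.0 * ctrl.area_um2, rel=1e-12)
    with pytest.raises(ValueError):
        aoe1_channel_rescaling(ctrl, RegionSpec("JP", 5.14, 2.13, 1.0, 0.2, {}))
    assert aoe1_channel_rescaling(ctrl, aoe, mode="length") == pytest.approx(
        1.3 / 6.15, rel=1e-12)


def test_total_channel_conductance_conserved_under_aoe1():
    """Per-node and per-JP voltage-gated conductance is identical between
    control and AOE1 (channel-number conservation)."""
    ctrl = discretize(build_axon("control"))
    aoe1 = discretize(build_axon("AOE1"))

    def per_region(cable, kind, arr):
        mask = cable.kind == kind
        return arr(cable)[mask].sum()

    for arr in (lambda c: c.g_na_us, lambda c: c.g_ht_us):
        a = per_region(ctrl, "node", arr) / 7
        b = per_region(aoe1, "node", arr) / 7
        assert b == pytest.approx(a, rel=1e-12)
    a = per_region(ctrl, "JP", lambda c: c.g_lt_us)
    b = per_region(aoe1, "JP", lambda c: c.g_lt_us)
    assert b == pytest.approx(a, rel=1e-12)


def test_nodal_capacitance_on_discretized_cable():
    ctrl = discretize(build_axon("control"))
    aoe = discretize(build_axon("AOE1"))
    c_node = ctrl.c_nf[ctrl.kind == "node"].sum() / 7 * 1e3  # nF -> pF
    assert c_node == pytest.approx(0.0327, abs=5e-5)
    c_node = aoe.c_nf[aoe.kind == "node"].sum() / 7 * 1e3
    assert c_node == pytest.approx(0.247, abs=5e-4)


def test_empty_affected_set_reproduces_control_cable():
    ctrl = discretize(build_axon("control"))
    sham = discretize(build_axon("AOE1", affected_inrs=[]))
    assert sham.equals(ctrl)


def test_build_rejects_bad_inputs():
    with pytest.raises(ValueError):
        build_axon("control", internode_length_um=10.0)  # PN/JP don't fit
    with pytest.raises(ValueError):
        build_axon("bogus")
    with pytest.raises(ValueError):
        build_axon("control", n_nodes=1)
    with pytest.raises(ValueError):
        build_axon("AOE1", affected_inrs=[9])
    with pytest.raises(ValueError):
        RegionSpec("n1", 1.0, 1.0, 1.0, 0.2, {"na": 5.0})


def test_discretize_respects_lambda_rule_and_conserves_length():
    spec = build_axon("control")
    cable = discretize(spec, max_lambda_fraction=0.1)
    total = sum(r.length_um for r in spec.regions)
    assert cable.length_um.sum() == pytest.approx(total, rel=1e-12)
    # per-compartment bound against the local region lambda
    i = 0
    for r in spec.regions:
        lam = region_lambda_um(r, spec.ra_ohm_cm)
        n = int(np.ceil(r.length_um / (0.1 * lam) - 1e-12))
        for _ in range(max(1, n)):
            assert cable.length_um[i] <= 0.1 * lam + 1e-9
            i += 1
    assert i == cable.n_comp
    assert np.all(cable.r_axial_mohm > 0)
    assert cable.area_cm2 == pytest.approx(
        np.pi * cable.diameter_um * cable.length_um * 1e-8, rel=1e-12)


def test_short_region_is_single_compartment_and_halving_doubles():
    params = ChannelParams(g_na=0.0, g_ht=0.0, g_lt=0.0)
    lam = region_lambda_um(RegionSpec("node", 1.0, 1.25, 1.0, 0.2, {}), 70.0)
    # a region exactly 10 sub-lengths long at f=0.1 splits 10 -> 20 on halving
    long_spec = AxonSpec(
        "control",
        (RegionSpec("node", 10 * 0.1 * lam, 1.25, 1.0, 0.2, {}),),
        1, 0.0, 70.0, frozenset(), params)
    assert discretize(long_spec, 0.1).n_comp == 10
    assert discretize(long_spec, 0.05).n_comp == 20
    short_spec = AxonSpec(
        "control", (RegionSpec("node", 1.3, 0.8, 1.0, 0.2, {}),),
        1, 0.0, 70.0, frozenset(), params)
    assert discretize(short_spec, 0.1).n_comp == 1


def test_axial_resistance_half_formula_regression():
    """Two adjacent 10 um x 1.25 um compartments at Ra 70 Ohm*cm."""
    params = ChannelParams(g_na=0.0, g_ht=0.0, g_lt=0.0)
    lam = region_lambda_um(RegionSpec("node", 1.0, 1.25, 1.0, 0.2, {}), 70.0)
    f = 10.5 / lam  # sub-length 10.5 um -> two 10 um compartments from 20 um
    spec = AxonSpec(
        "control", (RegionSpec("node", 20.0, 1.25, 1.0, 0.2, {}),),
        1, 0.0, 70.0, frozenset(), params)
    cable = discretize(spec, f)
    assert cable.n_comp == 2
    assert cable.length_um[0] == pytest.approx(10.0, rel=1e-12)
    assert cable.r_axial_mohm[0] == pytest.approx(5.70411316041353, rel=1e-12)


def test_rebuild_determinism_and_node_centers():
    a = discretize(build_axon("AOE2"))
    b = discretize(build_axon("AOE2"))
    assert a.equals(b)
    assert a.node_center_idx.size == 7
    assert all(a.kind[i] == "node" for i in a.node_center_idx)
    # node-center spacing = internode length + node length
    x = a.x_center_um[a.node_center_idx]
    assert np.diff(x) == pytest.approx(np.full(6, 100.0 + 1.3), rel=1e-9)


def test_cable_dataframe_schema(control_cable):
    df = control_cable.to_dataframe()
    assert list(df.columns[:5]) == ["index", "kind", "x_center_um", "length_um",
                                    "diameter_um"]
    assert len(df) == control_cable.n_comp
    assert df["r_axial_to_next_MOhm"].isna().sum() == 1  # last compartment only


def test_lt_current_location_switch():
    jp = discretize(build_axon("control", lt_location="JP"))
    pn = discretize(build_axon("control", lt_location="PN"))
    assert jp.g_lt_us[jp.kind == "JP"].sum() > 0
    assert jp.g_lt_us[jp.kind == "PN"].sum() == 0
    assert pn.g_lt_us[pn.kind == "PN"].sum() > 0
    assert pn.g_lt_us[pn.kind == "JP"].sum() == 0
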