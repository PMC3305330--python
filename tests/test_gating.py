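"""Gating energetics: ensembles, tension shifts and open-probability curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memcrowd as mc


def test_geometry_deltas_mscl(mscl_channel):
    dA, dC = mc.geometry_deltas(mscl_channel)
    assert dA == pytest.approx(math.pi * (3.5**2 - 2.4**2))
    assert dA == pytest.approx(20.389, abs=1e-3)
    assert dC == pytest.approx(2 * math.pi * 1.1)
    assert dC == pytest.approx(6.9115, abs=1e-4)


def test_geometry_deltas_degenerate_and_antisymmetric():
    same = mc.ChannelGeometry(3.0, 3.0)
    assert mc.geometry_deltas(same) == (0.0, 0.0)
    fwd = mc.ChannelGeometry(2.4, 3.5)
    rev = mc.ChannelGeometry(3.5, 2.4)
    assert mc.geometry_deltas(rev)[0] == pytest.approx(-fwd.delta_area)
    assert mc.geometry_deltas(rev)[1] == pytest.approx(-fwd.delta_circumference)


def test_mscl_gating_energies_match_reported_values(mscl_channel, mscl_mixture):
    """The four crowding energies for the half-packed MscL membrane:
    4.3 / 15.2 kBT (constant area, IG/SPT) and 1.1 / 2.2 kBT (constant
    tension, IG/SPT), at one-decimal precision."""
    ca_ig = mc.gating_energy_constant_area(mscl_channel, mscl_mixture, "ideal_gas")
    ca_spt = mc.gating_energy_constant_area(mscl_channel, mscl_mixture, "spt")
    ct_ig = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.0, "ideal_gas")
    ct_spt = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.0, "spt")
    assert round(ca_ig.crowding_energy, 1) == 4.3
    assert round(ca_spt.crowding_energy, 1) == 15.2
    assert round(ct_ig.crowding_energy, 1) == 1.1
    assert round(ct_spt.crowding_energy, 1) == 2.2


def test_mscl_gating_tension_shifts(mscl_channel, mscl_mixture):
    """Corresponding midpoint-tension increases: 0.21/0.74 and 0.05/0.11 kBT/nm^2."""
    shifts = {}
    for model in ("ideal_gas", "spt"):
        shifts[("area", model)] = mc.gating_tension_shift(
            mc.gating_energy_constant_area(mscl_channel, mscl_mixture, model)
        )
        shifts[("tension", model)] = mc.gating_tension_shift(
            mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.0, model)
        )
    assert round(shifts[("area", "ideal_gas")], 2) == 0.21
    assert round(shifts[("area", "spt")], 2) == 0.74
    assert round(shifts[("tension", "ideal_gas")], 2) == 0.05
    assert round(shifts[("tension", "spt")], 2) == 0.11


def test_no_crowders_means_no_crowding_energy(mscl_channel):
    empty = mc.CrowderMixture((1.0,), (1.0,), 0.0)
    for model in ("ideal_gas", "spt"):
        assert mc.gating_energy_constant_area(mscl_channel, empty, model).total == 0.0
        res = mc.gating_energy_constant_tension(mscl_channel, empty, 0.3, model)
        assert res.crowding_energy == 0.0
        assert res.loading_energy == pytest.approx(-0.3 * mscl_channel.delta_area)


def test_constant_tension_energy_vanishes_with_crowder_size(mscl_channel):
    """At fixed concentration, tau*dC -> 0 as the crowder radius -> 0."""
    energies = []
    for r in (1.0, 0.1, 0.01, 0.001):
        mix = mc.CrowderMixture((r,), (1.0,), 0.1)
        energies.append(
            mc.gating_energy_constant_tension(mscl_channel, mix, 0.0, "spt").crowding_energy
        )
    assert energies == sorted(energies, reverse=True)
    assert energies[-1] < 1e-2 * energies[0]


def test_loading_device_favors_opening(mscl_channel, mscl_mixture):
    res = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 1.0, "spt")
    assert res.loading_energy == pytest.approx(-mscl_channel.delta_area)
    assert res.total == pytest.approx(res.crowding_energy - mscl_channel.delta_area)


def test_spt_exceeds_ideal_gas_at_any_positive_packing(mscl_channel):
    for phi in (0.05, 0.2, 0.5, 0.7):
        mix = mc.CrowderMixture.uniform(1.0, area_fraction=phi)
        e_ig = mc.gating_energy_constant_area(mscl_channel, mix, "ideal_gas")
        e_spt = mc.gating_energy_constant_area(mscl_channel, mix, "spt")
        assert e_spt.crowding_energy > e_ig.crowding_energy


def test_mscl_spt_over_ig_ratios(mscl_channel, mscl_mixture):
    """Constant-tension SPT/IG ratio is exactly 1/(1-phi) = 2 at phi = 0.5;
    the constant-area ratio sits between the line (2x) and surface (4x)
    enhancements."""
    ca_ig = mc.gating_energy_constant_area(mscl_channel, mscl_mixture, "ideal_gas")
    ca_spt = mc.gating_energy_constant_area(mscl_channel, mscl_mixture, "spt")
    ct_ig = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.0, "ideal_gas")
    ct_spt = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.0, "spt")
    assert ct_spt.crowding_energy / ct_ig.crowding_energy == pytest.approx(2.0)
    ratio = ca_spt.crowding_energy / ca_ig.crowding_energy
    assert 2.0 < ratio < 4.0
    assert ratio == pytest.approx(3.49, abs=0.01)


def test_crowding_energy_antisymmetric_under_radius_swap(mscl_mixture):
    fwd = mc.ChannelGeometry(2.4, 3.5)
    rev = mc.ChannelGeometry(3.5, 2.4)
    for model in ("ideal_gas", "spt"):
        a = mc.gating_energy_constant_area(fwd, mscl_mixture, model)
        b = mc.gating_energy_constant_area(rev, mscl_mixture, model)
        assert b.crowding_energy == pytest.approx(-a.crowding_energy)


def test_constant_tension_crowding_depends_only_on_line_tension(mscl_channel, mscl_mixture):
    """The surface-tension term cancels at constant tension: the crowding
    energy equals tau_c*dC for either model's tau."""
    for model in ("ideal_gas", "spt"):
        res = mc.gating_energy_constant_tension(mscl_channel, mscl_mixture, 0.7, model)
        tau = mc.tensions_for(mscl_mixture, model).line_tension
        assert res.crowding_energy == pytest.approx(tau * mscl_channel.delta_circumference)


def test_gating_tension_shift_errors_for_zero_area_change(mscl_mixture):
    degenerate = mc.ChannelGeometry(3.0, 3.0)
    res = mc.gating_energy_constant_area(degenerate, mscl_mixture, "spt")
    with pytest.raises(ValueError):
        mc.gating_tension_shift(res)


# -- stepwise vs closed-form constant-tension route ------------------------


def test_decomposition_residual_scales_as_inverse_area(mscl_channel, mscl_mixture):
    r1 = mc.constant_tension_decomposition_check(mscl_channel, mscl_mixture, 0.5, 1e4)
    r2 = mc.constant_tension_decomposition_check(mscl_channel, mscl_mixture, 0.5, 1e8)
    assert abs(r2) < abs(r1)
    # O(1/A): a 10^4-fold larger membrane shrinks the residual ~10^4-fold
    assert abs(r2) == pytest.approx(abs(r1) * 1e-4, rel=0.5)


def test_decomposition_residual_small_at_cell_scale(mscl_channel, mscl_mixture):
    resid = mc.constant_tension_decomposition_check(mscl_channel, mscl_mixture, 0.0, 1e6)
    assert abs(resid) < 0.01


def test_decomposition_exact_without_crowders(mscl_channel):
    empty = mc.CrowderMixture((1.0,), (1.0,), 0.0)
    resid = mc.constant_tension_decomposition_check(mscl_channel, empty, 0.9, 1e5)
    assert resid == pytest.approx(0.0, abs=1e-12)


# -- open probability ------------------------------------------------------


def test_open_probability_half_at_bare_midpoint_without_crowders(mscl_channel):
    assert mc.open_probability(0.9, 0.9, mscl_channel, None) == pytest.approx(0.5)


def test_open_probability_sigmoid_limits(mscl_channel, mscl_mixture):
    sigma = np.linspace(0.0, 3.0, 50)
    p = mc.open_probability(sigma, 0.9, mscl_channel, mscl_mixture, "spt")
    assert np.all((p >= 0) & (p <= 1))
    # strictly increasing wherever the sigmoid is resolvable in floats
    interior = np.linspace(0.4, 1.6, 50)
    pi_ = mc.open_probability(interior, 0.9, mscl_channel, mscl_mixture, "spt")
    assert np.all(np.diff(pi_) > 0)
    assert mc.open_probability(50.0, 0.9, mscl_channel, mscl_mixture, "spt") > 1 - 1e-9


@given(
    sigma0=st.floats(0.0, 2.0),
    phi=st.floats(0.01, 0.7),
    r=st.floats(0.2, 3.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_midpoint_shift_equals_gating_tension_shift(sigma0, phi, r):
    """Algebraic identity: the P_open midpoint moves up by exactly the
    constant-tension gating-tension shift."""
    channel = mc.ChannelGeometry(2.4, 3.5)
    mix = mc.CrowderMixture.uniform(r, area_fraction=phi)
    for model in ("ideal_gas", "spt"):
        mid = mc.popen_midpoint(sigma0, channel, mix, model)
        shift = mc.gating_tension_shift(
            mc.gating_energy_constant_tension(channel, mix, sigma0, model)
        )
        assert mid - sigma0 == pytest.approx(shift, rel=1e-12, abs=1e-15)
        assert mc.open_probability(mid, sigma0, channel, mix, model) == pytest.approx(0.5)


def test_mscl_spt_midpoint_shift(mscl_channel, mscl_mixture):
    shift = mc.popen_midpoint(0.9, mscl_channel, mscl_mixture, "spt") - 0.9
    assert round(shift, 2) == 0.11
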