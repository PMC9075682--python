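"""Volume-probability profile construction and derived thicknesses."""

import dataclasses

import numpy as np
import pytest

import sdpfit as s
from sdpfit.profiles import GridExtentError, profiles_to_table
from sdpfit.volumetrics import CHAIN_MOIETIES, HEADGROUP_MOIETIES


def _integral(profiles, name):
    return np.trapezoid(profiles.components[name], profiles.z)


@pytest.mark.parametrize("name", ["DPPC", "POPC", "MSM"])
def test_moiety_normalization(name, solvent):
    """A·∫p_i dz = 2V_i for every moiety of the two-lipid unit cell."""
    lipid = s.builtin_lipid(name)
    params = s.template_structure(lipid)
    prof = s.build_profiles(params, lipid, solvent)
    for m in HEADGROUP_MOIETIES + ("CH3",):
        vol = lipid.moiety(m).volume
        assert params.A * _integral(prof, m) == \
            pytest.approx(2 * vol, rel=1e-6)
    # the slab holds everything except the terminal methyls
    slab_target = 2 * (lipid.V_HC - lipid.V_CH3)
    assert params.A * _integral(prof, "CH2") == \
        pytest.approx(slab_target, rel=1e-6)
    total = params.A * np.trapezoid(prof.total_lipid, prof.z)
    assert total == pytest.approx(2 * lipid.V_L, rel=1e-6)


def test_unit_cell_closure(dppc_profiles):
    gap = dppc_profiles.total_lipid + dppc_profiles.p_water - 1.0
    assert np.max(np.abs(gap[dppc_profiles.overfill == 0])) < 1e-9


def test_methyl_peak_reaches_one_at_sigma_zero(dppc, solvent):
    s0 = s.sigma_ch3_zero(63.1, dppc.V_CH3)
    params = dataclasses.replace(s.template_structure(dppc), sig_CH3=s0)
    prof = s.build_profiles(params, dppc, solvent)
    mid = np.argmin(np.abs(prof.z))
    assert prof.components["CH3"][mid] == pytest.approx(1.0, rel=1e-6)


def test_shell_off_equals_bulk_water_model(dppc, dppc_template):
    on = s.SolventSpec(V_BW=29.3)
    off = s.SolventSpec(V_BW=30.28)
    prof_on = s.build_profiles(dppc_template, dppc, on)
    prof_off = s.build_profiles(dppc_template, dppc, off)
    for probe in ("xray", "neutron"):
        d_on = s.contrast_profile(prof_on, dppc, on, probe)
        d_off = s.contrast_profile(prof_off, dppc, off, probe)
        no_shell = d_off  # V_BW = V_W: bound water indistinguishable
        assert np.allclose(d_off, no_shell)
        assert not np.allclose(d_on, d_off)  # the shell does something


def test_contrast_decays_to_zero_at_boundary(dppc, dppc_profiles, solvent):
    for probe in ("xray", "neutron"):
        drho = s.contrast_profile(dppc_profiles, dppc, solvent, probe)
        assert abs(drho[0]) < 1e-9 and abs(drho[-1]) < 1e-9


def test_neutron_chain_contrast_negative_in_d2o(dppc, dppc_profiles):
    drho = s.contrast_profile(dppc_profiles, dppc, s.SolventSpec(1.0),
                              "neutron")
    core = np.abs(dppc_profiles.z) < 5.0
    assert np.all(drho[core] < -4e-6)  # protiated chains vs D2O


def test_negative_water_zero_for_well_formed(dppc_profiles, solvent):
    assert s.negative_water(dppc_profiles, solvent) == 0.0


def test_negative_water_flags_forced_overlap(dppc, dppc_template, solvent):
    bloated = dataclasses.replace(dppc_template, z_CG=dppc_template.D_C(dppc)
                                  - 4.0, sig_CG=1.6)
    prof = s.build_profiles(bloated, dppc, solvent)
    assert prof.overfilled
    assert s.negative_water(prof, solvent) > 0


def _fabricated_profiles(A, p_water, overfill, z):
    params = s.StructureParams(A=A, z_CG=10, z_PCN=15, z_CholCH3=17,
                               sig_CG=2.4, sig_PCN=2.6, sig_CH3=2.9)
    return s.ProfileSet(z=z, components={}, shell=np.zeros_like(z),
                        p_water=p_water, overfill=overfill, params=params,
                        lipid_name="synthetic", d_c=14.0)


def test_negative_water_hand_integral(solvent):
    """Rectangular overlap, width 1 Å, excess 0.1, A = 60 Å²."""
    z = np.arange(-30, 30.05, 0.05)
    over = np.where(np.abs(z - 5.0) < 0.5, 0.1, 0.0)
    prof = _fabricated_profiles(60.0, np.zeros_like(z), over, z)
    assert s.negative_water(prof, solvent) == \
        pytest.approx(60 * 0.1 * 1.0 / 30.28, rel=1e-3)


def test_bound_water_hand_integral():
    """p_W = 0.5 over a 2 Å band per leaflet inside D_B at A = 63 Å²."""
    z = np.arange(-40, 40.05, 0.05)
    p_w = np.where(np.abs(z) >= 18.0, 1.0, 0.0) \
        + np.where((np.abs(z) >= 5.0) & (np.abs(z) < 7.0), 0.5, 0.0)
    prof = _fabricated_profiles(63.0, p_w, np.zeros_like(z), z)
    solvent = s.SolventSpec(V_BW=29.3)
    d_b = s.luzzati_thickness(prof)
    assert d_b == pytest.approx(36.0 - 2.0, rel=1e-3)
    assert s.bound_water_count(prof, solvent) == \
        pytest.approx(2 * 63.0 * 0.5 * 2.0 / 29.3, rel=1e-3)


def test_luzzati_identity_and_scaling(dppc, solvent):
    for area in (58.0, 63.1, 70.0):
        # rebuild the headgroup geometry for each area so nothing overfills
        params = s.template_structure(dppc, table={"A": area,
                                                   "sigma_CH3": 2.91})
        prof = s.build_profiles(params, dppc, solvent)
        assert s.luzzati_thickness(prof) == \
            pytest.approx(2 * dppc.V_L / area, rel=1e-6)


def test_bound_water_count_physical_range(dppc_profiles, solvent):
    """Saturated-PC hydration numbers fall in the reported ballpark."""
    n_w = s.bound_water_count(dppc_profiles, solvent)
    assert 5.0 < n_w < 16.0


def test_grid_extent_error(dppc, dppc_template, solvent):
    with pytest.raises(GridExtentError):
        s.build_profiles(dppc_template, dppc, solvent,
                         z=np.arange(-20, 20.1, 0.1))


def test_structure_params_validation():
    with pytest.raises(ValueError, match="ordering"):
        s.StructureParams(A=63, z_CG=20, z_PCN=15, z_CholCH3=22,
                          sig_CG=2.4, sig_PCN=2.6, sig_CH3=2.9).validate()
    with pytest.raises(ValueError):
        s.StructureParams(A=-1, z_CG=15, z_PCN=20, z_CholCH3=22,
                          sig_CG=2.4, sig_PCN=2.6, sig_CH3=2.9).validate()


def test_profile_export_is_self_describing(dppc, dppc_profiles, solvent):
    table = profiles_to_table(dppc_profiles, dppc, solvent)
    head = table.splitlines()[:6]
    assert any("A = 63.1" in line for line in head)
    assert any("V_BW" in line for line in head)
    ncols = len(table.splitlines()[-1].split("\t"))
    assert ncols == 10  # z, 5 moieties, p_W, S, two contrasts
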