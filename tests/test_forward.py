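"""Form-factor transforms, polydispersity averages and the vesicle shell."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erf
from scipy.stats import gamma as gamma_dist

import sdpfit as s
from sdpfit.forward import smear_gaussian, thin_shell_factor

Q = np.linspace(0.001, 0.6, 300)
Z = np.arange(-50, 50.05, 0.1)


def test_zero_profile_transforms_to_zero():
    assert np.all(s.bilayer_form_factor(np.zeros_like(Z), Z, Q) == 0)


def test_gaussian_transform_oracle():
    c, sig = 2.3e-3, 3.0
    profile = c * np.exp(-0.5 * (Z / sig) ** 2)
    f = s.bilayer_form_factor(profile, Z, Q)
    exact = c * sig * np.sqrt(2 * np.pi) * np.exp(-0.5 * (Q * sig) ** 2)
    assert np.max(np.abs(f - exact)) < 1e-6 * np.max(np.abs(exact))


def test_smeared_slab_transform_oracle():
    rho0, half, sig = 1.7e-3, 14.0, 2.5
    arg = np.sqrt(2) * sig
    profile = 0.5 * rho0 * (erf((half - Z) / arg) + erf((half + Z) / arg))
    f = s.bilayer_form_factor(profile, Z, Q)
    exact = 2 * rho0 * np.sin(Q * half) / Q * np.exp(-0.5 * (Q * sig) ** 2)
    assert np.max(np.abs(f - exact)) < 1e-6 * np.max(np.abs(exact))


def test_form_factor_at_zero_equals_profile_integral():
    profile = 1e-3 * np.exp(-0.5 * (Z / 4.0) ** 2)
    f0 = s.bilayer_form_factor(profile, Z, np.array([1e-9]))[0]
    assert f0 == pytest.approx(np.trapezoid(profile, Z), rel=1e-9)


def test_non_decayed_profile_warns():
    with pytest.warns(UserWarning, match="not decayed"):
        s.bilayer_form_factor(np.ones_like(Z), Z, Q)


class TestThicknessPolydispersity:
    def test_zero_width_reduces_to_single_structure(self, dppc, solvent):
        params = dataclasses.replace(s.template_structure(dppc), s_poly=0.0)
        prof = s.build_profiles(params, dppc, solvent, z=Z)
        f = s.bilayer_form_factor(
            s.contrast_profile(prof, dppc, solvent, "xray"), Z, Q)
        poly = s.polydisperse_intensity(params, dppc, solvent, "xray", Q,
                                        z=Z)
        assert np.allclose(poly, f ** 2, rtol=1e-12)

    def test_two_node_quadrature_is_arithmetic_mean(self, dppc, solvent):
        params = dataclasses.replace(s.template_structure(dppc), s_poly=1.0)
        d_c0 = params.D_C(dppc)
        halves = []
        for d_c in (d_c0 - 1.0, d_c0 + 1.0):
            prof = s.build_profiles(params, dppc, solvent, z=Z, d_c=d_c,
                                    headgroup_shift=d_c - d_c0)
            f = s.bilayer_form_factor(
                s.contrast_profile(prof, dppc, solvent, "xray"), Z, Q)
            halves.append(f ** 2)
        two_node = s.polydisperse_intensity(params, dppc, solvent, "xray",
                                            Q, n_nodes=2, z=Z)
        assert np.allclose(two_node, 0.5 * (halves[0] + halves[1]),
                           rtol=1e-10)

    def test_polydispersity_fills_minima(self, dppc, solvent):
        mono = dataclasses.replace(s.template_structure(dppc), s_poly=0.0)
        poly = dataclasses.replace(mono, s_poly=1.2)
        i_mono = s.polydisperse_intensity(mono, dppc, solvent, "neutron", Q,
                                          z=Z)
        i_poly = s.polydisperse_intensity(poly, dppc, solvent, "neutron", Q,
                                          z=Z)
        interior = np.arange(1, Q.size - 1)
        minima = interior[(i_mono[1:-1] < i_mono[:-2])
                          & (i_mono[1:-1] < i_mono[2:])]
        assert minima.size > 0
        assert np.all(i_poly[minima] > i_mono[minima])

    def test_unphysical_width_rejected(self, dppc, solvent):
        params = dataclasses.replace(s.template_structure(dppc), s_poly=6.0)
        with pytest.raises(ValueError, match="unphysical"):
            s.polydisperse_intensity(params, dppc, solvent, "xray", Q)


class TestThinShell:
    def test_monodisperse_zeros_at_qr_multiples_of_pi(self):
        ves = s.VesicleSpec(radius=550.0, polydispersity=0.0)
        q_zero = np.array([np.pi / 550.0, 2 * np.pi / 550.0])
        assert np.all(thin_shell_factor(ves, q_zero) < 1e-20)

    def test_poly_to_zero_limit_matches_monodisperse(self):
        q = np.linspace(0.002, 0.3, 500)
        mono = thin_shell_factor(s.VesicleSpec(550.0, 0.0), q)
        tiny = thin_shell_factor(s.VesicleSpec(550.0, 1e-4), q)
        assert np.allclose(tiny, mono, atol=1e-4 * mono.max())

    def test_schulz_average_matches_numeric_quadrature(self):
        """Closed-form gamma average vs brute-force integration."""
        r_bar, p = 550.0, 0.25
        k = 1.0 / p ** 2
        theta = r_bar * p ** 2
        ves = s.VesicleSpec(r_bar, p)
        q_test = np.array([0.004, 0.01, 0.03, 0.08])
        for q in q_test:
            num = quad(lambda r: gamma_dist.pdf(r, k, scale=theta)
                       * r ** 2 * np.sin(q * r) ** 2, 0, 6 * r_bar,
                       limit=400)[0]
            m4 = k * (k + 1) * (k + 2) * (k + 3) * theta ** 4
            expected = num / (q ** 2 * m4)
            assert thin_shell_factor(ves, np.array([q]))[0] == \
                pytest.approx(expected, rel=1e-6)

    def test_vesicle_validation(self):
        with pytest.raises(ValueError):
            s.VesicleSpec(radius=-5)
        with pytest.raises(ValueError):
            s.VesicleSpec(polydispersity=0.7)
        with pytest.raises(ValueError):
            s.VesicleSpec(radius=300.0).validate_against(d_b=40.0)


class TestInstrument:
    def test_identity(self):
        i = np.linspace(1, 2, 50)
        out = s.apply_instrument(i, s.InstrumentSpec())
        assert np.allclose(out, i)

    def test_background_dominates_decayed_signal(self):
        q = np.linspace(0.01, 0.6, 200)
        signal = 1e-3 * np.exp(-((q / 0.05) ** 2))
        inst = s.InstrumentSpec(scale=1.0, background=0.37)
        assert s.apply_instrument(signal, inst)[-1] == \
            pytest.approx(0.37, rel=1e-6)

    def test_boxcar_smearing_conserves_integral(self):
        q = np.linspace(0.01, 0.6, 1200)
        box = np.where(np.abs(q - 0.3) < 0.05, 1.0, 0.0)
        smeared = smear_gaussian(box, q, np.full_like(q, 0.004))
        assert np.trapezoid(smeared, q) == \
            pytest.approx(np.trapezoid(box, q), rel=1e-6)

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            s.InstrumentSpec(scale=0.0)
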