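"""Joint cost function, optimizer behavior and the ensemble sampler."""

import dataclasses

import numpy as np
import pytest

import sdpfit as s
from sdpfit.fitting import JointModel, sample_bounded


def _dataset(probe, q0, q1, n, d2o=1.0):
    q = np.linspace(q0, q1, n)
    return s.Dataset(probe=probe, d2o_fraction=d2o, q=q,
                     intensity=np.ones_like(q), sigma=np.ones_like(q))


def _experiment(dppc, datasets):
    return s.Experiment(lipid=dppc, solvent=s.SolventSpec(),
                        vesicle=s.VesicleSpec(), datasets=datasets)


class TestAlphaWeight:
    def test_equal_densities_single_contrast(self, dppc):
        exp = _experiment(dppc, [_dataset("xray", 0.01, 0.51, 250),
                                 _dataset("neutron", 0.05, 0.30, 125)])
        assert s.alpha_weight(exp) == pytest.approx(1.0)

    def test_direct_evaluation(self, dppc):
        exp = _experiment(dppc, [_dataset("xray", 0.01, 0.51, 500),
                                 _dataset("neutron", 0.05, 0.30, 250)])
        assert s.alpha_weight(exp) == pytest.approx(1.0)

    def test_two_identical_neutron_sets_halve_alpha(self, dppc):
        exp = _experiment(dppc, [_dataset("xray", 0.01, 0.51, 500),
                                 _dataset("neutron", 0.05, 0.30, 250, 1.0),
                                 _dataset("neutron", 0.05, 0.30, 250, 0.75)])
        assert s.alpha_weight(exp) == pytest.approx(0.5)

    def test_needs_both_probes(self, dppc):
        exp = _experiment(dppc, [_dataset("xray", 0.01, 0.51, 100)])
        with pytest.raises(ValueError):
            s.alpha_weight(exp)


class TestDatasetValidation:
    def test_q_range(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _dataset("xray", 0.5, 0.1, 10)
        q = np.linspace(0.5, 1.5, 10)
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            s.Dataset(probe="xray", d2o_fraction=1.0, q=q,
                      intensity=np.ones(10), sigma=np.ones(10))

    def test_positive_uncertainties(self):
        q = np.linspace(0.01, 0.5, 10)
        with pytest.raises(ValueError, match="> 0"):
            s.Dataset(probe="xray", d2o_fraction=1.0, q=q,
                      intensity=np.ones(10), sigma=np.zeros(10))


class TestTotalCost:
    def test_perfect_model_costs_only_penalty(self, small_experiment, dppc):
        truth, exp = small_experiment
        clean = s.joint_model_intensities(truth, exp)
        saved = [(ds.intensity, ds.instrument) for ds in exp.datasets]
        try:
            for ds, model, inst in zip(exp.datasets, clean,
                                       exp.truth_instruments):
                ds.intensity = inst.scale * model + inst.background
                ds.instrument = inst
            chi = s.total_cost(truth, exp)
            assert chi.chi_xray == pytest.approx(0.0, abs=1e-12)
            assert chi.chi_neutron == pytest.approx(0.0, abs=1e-12)
            assert chi.n_h2o == 0.0       # no overfill for the drawn truth
            assert chi.total == pytest.approx(0.0, abs=1e-12)
        finally:
            for ds, (intensity, inst) in zip(exp.datasets, saved):
                ds.intensity = intensity
                ds.instrument = inst

    def test_penalty_is_squared_negative_water(self, small_experiment,
                                               dppc):
        truth, exp = small_experiment
        overfilled = dataclasses.replace(
            truth, z_CG=truth.D_C(dppc) - 4.0, sig_CG=1.6)
        cfg = s.FitConfig(sigma_H2O=1.0)
        chi = s.total_cost(overfilled, exp, cfg)
        assert chi.n_h2o > 0
        assert chi.penalty == pytest.approx(chi.n_h2o ** 2)
        half = s.total_cost(overfilled, exp, s.FitConfig(sigma_H2O=2.0))
        assert half.penalty == pytest.approx(chi.penalty / 4.0)

    def test_doubling_uncertainties_quarters_chi2(self, small_experiment):
        truth, exp = small_experiment
        chi1 = s.total_cost(truth, exp)
        saved = [ds.sigma for ds in exp.datasets]
        try:
            for ds in exp.datasets:
                ds.sigma = 2.0 * ds.sigma
            chi2 = s.total_cost(truth, exp)
        finally:
            for ds, sig in zip(exp.datasets, saved):
                ds.sigma = sig
        assert chi2.chi_xray == pytest.approx(chi1.chi_xray / 4, rel=1e-9)
        assert chi2.chi_neutron == pytest.approx(chi1.chi_neutron / 4,
                                                 rel=1e-9)

    def test_decomposition_identity(self, small_experiment):
        truth, exp = small_experiment
        chi = s.total_cost(truth, exp)
        assert chi.total == pytest.approx(
            chi.chi_xray + chi.alpha * chi.chi_neutron + chi.penalty,
            rel=1e-12)


class TestFit:
    def test_truth_is_a_fixed_point_without_noise(self, dppc):
        design = s.ExperimentDesign(q_xray=np.linspace(0.01, 0.6, 120),
                                    q_neutron=np.linspace(0.01, 0.3, 60),
                                    noise_rel_xray=0.0,
                                    noise_rel_neutron=0.0,
                                    background_rel=0.0)
        truth = s.make_truth(dppc, seed=21)
        exp = s.simulate_experiment(truth, dppc, design, seed=22, n_sans=1)
        cfg = s.FitConfig(max_nfev=60)
        res = s.fit(exp, cfg, start=truth)
        for name in ("A", "z_CG", "z_PCN", "sig_CH3", "s_poly"):
            assert getattr(res.params, name) == \
                pytest.approx(getattr(truth, name), rel=1e-4)
        assert res.chi2.total < 1e-10

    def test_reported_chi2_is_reproducible(self, small_experiment):
        truth, exp = small_experiment
        cfg = s.FitConfig(max_nfev=40)
        res = s.fit(exp, cfg)
        again = res.model.chi_square(res.x).total
        assert res.chi2.total == pytest.approx(again, rel=1e-8)

    def test_optimizer_leaves_overfilled_region(self, small_experiment,
                                                dppc):
        truth, exp = small_experiment
        bad_start = dataclasses.replace(
            truth, z_CG=truth.D_C(dppc) - 4.0, sig_CG=1.6)
        cfg = s.FitConfig(max_nfev=30)
        n0 = s.total_cost(bad_start, exp, cfg).n_h2o
        assert n0 > 0
        res = s.fit(exp, cfg, start=bad_start)
        assert res.chi2.n_h2o < n0
        assert res.chi2.total <= s.total_cost(bad_start, exp, cfg).total


class TestSampler:
    def test_fixed_seed_reproduces_draws(self):
        def logp(x):
            return -0.5 * float(x @ x)
        lb, ub = np.full(2, -5.0), np.full(2, 5.0)
        a = sample_bounded(logp, np.zeros(2), lb, ub, n_steps=200,
                           n_burn=50, seed=42)
        b = sample_bounded(logp, np.zeros(2), lb, ub, n_steps=200,
                           n_burn=50, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_correlation_map_independent_gaussians(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((10_000, 2))
        *_, r = s.correlation_map(draws, (0, 1))
        assert abs(r) < 0.05

    def test_correlation_map_recovers_known_r(self):
        rng = np.random.default_rng(1)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        draws = rng.multivariate_normal([0, 0], cov, size=40_000)
        hist, xe, ye, r = s.correlation_map(draws, (0, 1))
        assert r == pytest.approx(0.8, abs=0.02)
        dx, dy = np.diff(xe)[:, None], np.diff(ye)[None, :]
        assert float((hist * dx * dy).sum()) == pytest.approx(1.0, rel=1e-6)

    def test_correlation_map_errors(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((500, 2))
        with pytest.raises(ValueError, match="1000"):
            s.correlation_map(draws, (0, 1))
        const = np.column_stack([np.ones(2000),
                                 rng.standard_normal(2000)])
        with pytest.raises(ValueError, match="constant"):
            s.correlation_map(const, (0, 1))


def test_joint_model_parameter_packing(small_experiment, dppc):
    _, exp = small_experiment
    cfg = s.FitConfig(fit_V_BW=True, fit_V_H=True)
    model = JointModel(exp, cfg)
    assert "V_BW" in model.names and "V_H" in model.names
    assert f"scale_{len(exp.datasets) - 1}" in model.names
    params, lipid, solvent, instruments = model.unpack(model.x0)
    assert solvent.V_BW == pytest.approx(29.3)
    assert lipid.V_H == pytest.approx(328.0)
    x = model.x0.copy()
    x[model.names.index("V_H")] = 310.0
    _, lipid2, _, _ = model.unpack(x)
    assert lipid2.V_H == pytest.approx(310.0)
    assert lipid2.V_HC == pytest.approx(lipid.V_HC)
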