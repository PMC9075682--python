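"""Joint multi-contrast SAXS/SANS parameter estimation.

One X-ray and N neutron datasets share a single trans-bilayer structure;
only scale and constant background are per-dataset.  The cost is

    χ² = χ_X² + α χ_N² + (n_H2O/σ_H2O)²,

where α equalizes the q-space point densities of the two probes and the
last term penalizes "negative water" (overfilled unit cells).  Point
estimates come from bounded trust-region-reflective least squares; parameter
correlations from a seeded affine-invariant ensemble sampler targeting
exp(−χ²/2) with flat priors inside the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import emcee
import numpy as np
from scipy.optimize import least_squares

from . import chains
from .forward import InstrumentSpec, VesicleSpec, _poly_nodes, \
    smear_gaussian, thin_shell_factor
from .profiles import StructureParams, build_profiles, bound_water_count, \
    contrast_profile, luzzati_thickness, negative_water, template_structure
from .volumetrics import LipidSpec, SolventSpec

STRUCTURE_FREE = ("A", "z_CG", "z_PCN", "z_CholCH3", "sig_CG", "sig_PCN",
                  "sig_CH3", "s_poly")

DEFAULT_BOUNDS = {
    "A": (45.0, 90.0),
    "z_CG": (5.0, 35.0),
    "z_PCN": (5.0, 35.0),
    "z_CholCH3": (5.0, 35.0),
    "sig_CG": (1.5, 6.0),
    "sig_PCN": (1.5, 6.0),
    "sig_CH3": (1.5, 6.0),
    "s_poly": (0.0, 3.5),
    "V_BW": (27.0, 30.28),
    "V_H": (295.0, 365.0),
    "scale": (1e-3, 1e3),
    # negative values allowed: solvent over-subtraction is common
    "background": (-1e3, 1e3),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """One measured (or simulated) scattering curve."""

    probe: str
    d2o_fraction: float
    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    sigma_q: np.ndarray | None = None
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)

    def __post_init__(self) -> None:
        if self.probe not in ("xray", "neutron"):
            raise ValueError(f"probe must be 'xray' or 'neutron', got "
                             f"{self.probe!r}")
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        self.sigma = np.asarray(self.sigma, float)
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("q, intensity and sigma must share one length")
        if self.sigma_q is not None:
            self.sigma_q = np.asarray(self.sigma_q, float)
            if self.sigma_q.shape != self.q.shape:
                raise ValueError("sigma_q length mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q[0] <= 0 or self.q[-1] > 1.0:
            raise ValueError("q must lie in (0, 1] Å⁻¹")
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be > 0")

    @property
    def q_density(self) -> float:
        """Points per unit q [Å]."""
        return self.q.size / (self.q[-1] - self.q[0])


@dataclass
class Experiment:
    """A joint campaign: one lipid, one vesicle population, many contrasts."""

    lipid: LipidSpec
    solvent: SolventSpec
    vesicle: VesicleSpec
    datasets: list[Dataset]

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("experiment needs at least one dataset")

    @property
    def xray(self) -> list[Dataset]:
        return [d for d in self.datasets if d.probe == "xray"]

    @property
    def neutron(self) -> list[Dataset]:
        return [d for d in self.datasets if d.probe == "neutron"]


@dataclass
class ChiSquare:
    chi_xray: float
    chi_neutron: float
    penalty: float
    alpha: float
    n_h2o: float

    @property
    def total(self) -> float:
        return self.chi_xray + self.alpha * self.chi_neutron + self.penalty


def alpha_weight(experiment: Experiment,
                 pooling: str = "per_dataset") -> float:
    """Probe-balance weight α: X-ray point density over total neutron one.

    α = [n_X/(q_X^max − q_X^min)] / [N_N · n_N/(q_N^max − q_N^min)].  With
    several neutron contrasts the per-dataset densities are averaged
    (``pooling='per_dataset'``, assuming similar densities) or the points are
    pooled over the union range (``pooling='pooled'``).
    """
    if not experiment.xray or not experiment.neutron:
        raise ValueError("α needs at least one X-ray and one neutron dataset")
    xr = experiment.xray[0]
    if xr.q[-1] - xr.q[0] <= 0:
        raise ValueError("zero-width X-ray q-range")
    dens_x = xr.q_density
    neutron = experiment.neutron
    n_n = len(neutron)
    if pooling == "per_dataset":
        dens_n = float(np.mean([d.q_density for d in neutron]))
    elif pooling == "pooled":
        total = sum(d.q.size for d in neutron)
        span = max(d.q[-1] for d in neutron) - min(d.q[0] for d in neutron)
        dens_n = total / span / n_n
    else:
        raise ValueError("pooling must be 'per_dataset' or 'pooled'")
    return dens_x / (n_n * dens_n)


# ---------------------------------------------------------------------------
# joint model
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Free-parameter selection, bounds, penalty and sampler settings."""

    free: tuple[str, ...] = STRUCTURE_FREE
    fit_scale: bool = True
    fit_background: bool = True
    fit_V_BW: bool = False
    fit_V_H: bool = False
    bounds: dict = field(default_factory=dict)
    start: dict = field(default_factory=dict)
    sigma_H2O: float = 0.1
    seed: int = 0
    n_walkers: int = 32
    n_steps: int = 1000
    n_burn: int = 250
    poly_nodes: int = 11
    shell_mode: str = "choline_plus_shell"
    alpha_pooling: str = "per_dataset"
    z_max: float = 50.0
    dz: float = 0.1
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_H2O <= 0:
            raise ValueError("sigma_H2O must be > 0")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with "
                                 f"lo < hi")


class JointModel:
    """Cached forward model + cost for one experiment.

    The z-grid and the per-dataset cosine-transform matrices are fixed once,
    so a cost evaluation reduces to cheap special-function profile builds
    and small matrix products.
    """

    def __init__(self, experiment: Experiment, config: FitConfig,
                 start: StructureParams | None = None):
        self.experiment = experiment
        self.config = config
        n = int(round(config.z_max / config.dz))
        self.z = np.arange(-n, n + 1) * config.dz
        w = np.full_like(self.z, config.dz)
        w[0] = w[-1] = 0.5 * config.dz
        self._cos = [np.cos(np.outer(ds.q, self.z)) * w
                     for ds in experiment.datasets]
        self._shell_t = [thin_shell_factor(experiment.vesicle, ds.q)
                         for ds in experiment.datasets]
        self.alpha = (alpha_weight(experiment, config.alpha_pooling)
                      if experiment.xray and experiment.neutron else 1.0)
        self.template = start if start is not None \
            else template_structure(experiment.lipid)

        names: list[str] = list(config.free)
        if config.fit_V_BW:
            names.append("V_BW")
        if config.fit_V_H:
            names.append("V_H")
        for i, _ in enumerate(experiment.datasets):
            if config.fit_scale:
                names.append(f"scale_{i}")
            if config.fit_background:
                names.append(f"background_{i}")
        self.names = tuple(names)
        self.lb, self.ub, self.x0 = self._assemble_bounds()

    # -- parameter vector ---------------------------------------------------
    def _default_start(self, name: str) -> float:
        if name in STRUCTURE_FREE:
            return getattr(self.template, name)
        if name == "V_BW":
            return self.experiment.solvent.V_BW
        if name == "V_H":
            return self.experiment.lipid.V_H
        kind, idx = name.rsplit("_", 1)
        inst = self.experiment.datasets[int(idx)].instrument
        return getattr(inst, kind)

    def _assemble_bounds(self):
        lb, ub, x0 = [], [], []
        for name in self.names:
            base = name.rsplit("_", 1)[0] \
                if name.startswith(("scale_", "background_")) else name
            lo, hi = self.config.bounds.get(name,
                                            DEFAULT_BOUNDS.get(base,
                                                               (-np.inf,
                                                                np.inf)))
            start = self.config.start.get(name, self._default_start(name))
            if base == "background" and start <= 0:
                start = 0.0
            lb.append(lo)
            ub.append(hi)
            x0.append(float(np.clip(start, lo, hi)))
        return np.array(lb), np.array(ub), np.array(x0)

    def unpack(self, x: np.ndarray):
        vals = dict(zip(self.names, x))
        params = replace(self.template,
                         **{k: vals[k] for k in STRUCTURE_FREE
                            if k in vals})
        solvent = self.experiment.solvent
        if "V_BW" in vals:
            solvent = replace(solvent, V_BW=float(vals["V_BW"]))
        lipid = self.experiment.lipid
        if "V_H" in vals:
            lipid = lipid.with_headgroup_volume(float(vals["V_H"]))
        instruments = []
        for i, ds in enumerate(self.experiment.datasets):
            inst = ds.instrument
            if f"scale_{i}" in vals:
                inst = replace(inst, scale=float(vals[f"scale_{i}"]))
            if f"background_{i}" in vals:
                inst = replace(inst, background=float(vals[f"background_{i}"]))
            instruments.append(inst)
        return params, lipid, solvent, instruments

    # -- forward model ------------------------------------------------------
    def raw_intensities(self, params: StructureParams,
                        lipid: LipidSpec | None = None,
                        solvent: SolventSpec | None = None
                        ) -> list[np.ndarray]:
        """Vesicle-shape × bilayer intensity per dataset (no scale/bg)."""
        lipid = lipid if lipid is not None else self.experiment.lipid
        solvent = solvent if solvent is not None else self.experiment.solvent
        d_c0 = params.D_C(lipid)
        if params.s_poly > 0:
            nodes, w = _poly_nodes(d_c0, params.s_poly,
                                   self.config.poly_nodes)
        else:
            nodes, w = np.array([d_c0]), np.array([1.0])
        profs = [build_profiles(params, lipid, solvent, z=self.z,
                                shell_mode=self.config.shell_mode,
                                d_c=d_ci, headgroup_shift=d_ci - d_c0)
                 for d_ci in nodes]
        out = []
        for i, ds in enumerate(self.experiment.datasets):
            sol = replace(solvent, d2o_fraction=ds.d2o_fraction) \
                if ds.probe == "neutron" else solvent
            acc = np.zeros(ds.q.size)
            for prof, wi in zip(profs, w):
                drho = contrast_profile(prof, lipid, sol, ds.probe)
                f = self._cos[i] @ drho
                acc += wi * f * f
            out.append(self._shell_t[i] * acc)
        return out

    def central_profiles(self, params: StructureParams,
                         lipid: LipidSpec | None = None,
                         solvent: SolventSpec | None = None):
        lipid = lipid if lipid is not None else self.experiment.lipid
        solvent = solvent if solvent is not None else self.experiment.solvent
        return build_profiles(params, lipid, solvent, z=self.z,
                              shell_mode=self.config.shell_mode)

    def model_curves(self, x: np.ndarray) -> list[np.ndarray]:
        params, lipid, solvent, instruments = self.unpack(x)
        raw = self.raw_intensities(params, lipid, solvent)
        out = []
        for ds, inst, curve in zip(self.experiment.datasets, instruments,
                                   raw):
            if inst.smearing:
                sq = ds.sigma_q if ds.sigma_q is not None \
                    else inst.dq_rel * ds.q
                curve = smear_gaussian(curve, ds.q, sq)
            out.append(inst.scale * curve + inst.background)
        return out

    # -- cost ---------------------------------------------------------------
    def residual_vector(self, x: np.ndarray) -> np.ndarray:
        params, lipid, solvent, instruments = self.unpack(x)
        curves = self.model_curves(x)
        parts = []
        sqrt_alpha = np.sqrt(self.alpha)
        for ds, curve in zip(self.experiment.datasets, curves):
            if not np.all(np.isfinite(curve)):
                bad = ds.q[~np.isfinite(curve)]
                raise FloatingPointError(
                    f"non-finite model intensity at q = {bad[:5]} Å⁻¹")
            r = (curve - ds.intensity) / ds.sigma
            parts.append(r if ds.probe == "xray" else sqrt_alpha * r)
        prof = self.central_profiles(params, lipid, solvent)
        n_h2o = negative_water(prof, solvent)
        parts.append(np.array([n_h2o / self.config.sigma_H2O]))
        return np.concatenate(parts)

    def chi_square(self, x: np.ndarray) -> ChiSquare:
        params, lipid, solvent, instruments = self.unpack(x)
        curves = self.model_curves(x)
        chi_x = chi_n = 0.0
        for ds, curve in zip(self.experiment.datasets, curves):
            c = float(np.sum(((curve - ds.intensity) / ds.sigma) ** 2))
            if ds.probe == "xray":
                chi_x += c
            else:
                chi_n += c
        prof = self.central_profiles(params, lipid, solvent)
        n_h2o = negative_water(prof, solvent)
        return ChiSquare(chi_xray=chi_x, chi_neutron=chi_n,
                         penalty=(n_h2o / self.config.sigma_H2O) ** 2,
                         alpha=self.alpha, n_h2o=n_h2o)


def joint_model_intensities(params: StructureParams, experiment: Experiment,
                            config: FitConfig | None = None
                            ) -> list[np.ndarray]:
    """Raw (unit-scale, zero-background) model curves for each dataset."""
    config = config or FitConfig()
    return JointModel(experiment, config, start=params) \
        .raw_intensities(params)


def total_cost(params: StructureParams, experiment: Experiment,
               config: FitConfig | None = None,
               instruments: list[InstrumentSpec] | None = None
               ) -> ChiSquare:
    """χ² = χ_X² + α χ_N² + (n_H2O/σ_H2O)² at the given structure."""
    config = config or FitConfig()
    model = JointModel(experiment, config, start=params)
    if instruments is not None:
        for ds, inst in zip(experiment.datasets, instruments):
            ds.instrument = inst
    x = model.x0.copy()
    for i, name in enumerate(model.names):
        if name in STRUCTURE_FREE:
            x[i] = getattr(params, name)
    return model.chi_square(x)


# ---------------------------------------------------------------------------
# point estimation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: StructureParams
    instruments: list[InstrumentSpec]
    V_BW: float
    V_H: float
    chi2: ChiSquare
    derived: dict
    names: tuple[str, ...]
    x: np.ndarray
    perr: np.ndarray
    success: bool
    message: str
    nfev: int
    model: JointModel

    def uncertainty(self, name: str) -> float:
        return float(self.perr[self.names.index(name)])

    def value(self, name: str) -> float:
        return float(self.x[self.names.index(name)])


def _derived_quantities(model: JointModel, x: np.ndarray) -> dict:
    params, lipid, solvent, _ = model.unpack(x)
    prof = model.central_profiles(params, lipid, solvent)
    d_c = params.D_C(lipid)
    s0 = chains.sigma_ch3_zero(params.A, lipid.V_CH3)
    out = {
        "A": params.A,
        "D_B": luzzati_thickness(prof),
        "2D_C": 2.0 * d_c,
        "sigma_CH3": params.sig_CH3,
        "sigma_CH3_0": s0,
        "n_W": bound_water_count(prof, solvent),
        "n_H2O": negative_water(prof, solvent),
    }
    try:
        out["upsilon"] = chains.upsilon(params.sig_CH3, d_c, s0)
    except ValueError:
        out["upsilon"] = float("nan")
    return out


def fit(experiment: Experiment, config: FitConfig | None = None,
        start: StructureParams | None = None) -> FitResult:
    """Bounded trust-region-reflective least squares on the joint cost.

    Deterministic given start values.  Non-convergence is flagged on the
    result (``success=False`` with the solver message), never silent.
    """
    config = config or FitConfig()
    model = JointModel(experiment, config, start=start)
    res = least_squares(model.residual_vector, model.x0, bounds=(model.lb,
                        model.ub), method="trf", x_scale="jac",
                        max_nfev=config.max_nfev)
    # covariance from the SVD of the column-normalized weighted jacobian
    # (stable against both the squared conditioning of JᵀJ and the very
    # different parameter scales); rank-deficient directions get inf
    cn = np.linalg.norm(res.jac, axis=0)
    cn[cn == 0] = 1.0
    _, sv, vt = np.linalg.svd(res.jac / cn, full_matrices=False)
    keep = sv > np.finfo(float).eps * max(res.jac.shape) * sv[0]
    cov_scaled = (vt[keep].T / sv[keep] ** 2) @ vt[keep]
    perr = np.sqrt(np.clip(np.diag(cov_scaled), 0.0, None)) / cn
    if not np.all(keep):
        null = (vt[~keep] ** 2).sum(axis=0) > 1e-12
        perr[null] = np.inf
    params, lipid, solvent, instruments = model.unpack(res.x)
    return FitResult(
        params=params, instruments=instruments, V_BW=solvent.V_BW,
        V_H=lipid.V_H, chi2=model.chi_square(res.x),
        derived=_derived_quantities(model, res.x),
        names=model.names, x=res.x, perr=perr,
        success=bool(res.success), message=res.message, nfev=res.nfev,
        model=model)


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    names: tuple[str, ...]
    samples: np.ndarray           # (n_draws, n_dim), burn-in removed
    acceptance_fraction: float
    autocorr_time: np.ndarray | None
    n_walkers: int
    n_steps: int
    seed: int

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]


def sample_bounded(log_prob, x0: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                   n_walkers: int = 32, n_steps: int = 1000,
                   n_burn: int = 250, seed: int = 0,
                   names: tuple[str, ...] | None = None) -> PosteriorResult:
    """Seeded affine-invariant ensemble sampling inside a box.

    Targets ``log_prob`` with flat priors inside [lb, ub]; walkers start in
    a small Gaussian ball around ``x0``.  Fixed seed → identical draws.
    """
    ndim = x0.size
    n_walkers = max(n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(seed)
    span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)
    # ball width follows the start value, with a tiny span-based floor so no
    # dimension starts collapsed (the affine-invariant moves cannot expand a
    # dimension in which every walker agrees)
    spread = 1e-3 * np.abs(x0) + 1e-9 * span
    p0 = x0 + spread * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, lb + 1e-9 * span, ub - 1e-9 * span)

    def bounded(x):
        if np.any(x < lb) or np.any(x > ub):
            return -np.inf
        return log_prob(x)

    sampler = emcee.EnsembleSampler(n_walkers, ndim, bounded)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    try:
        tau = sampler.get_autocorr_time(quiet=True)
    except Exception:
        tau = None
    return PosteriorResult(
        names=names or tuple(f"x{i}" for i in range(ndim)),
        samples=sampler.get_chain(discard=n_burn, flat=True),
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        autocorr_time=tau, n_walkers=n_walkers, n_steps=n_steps, seed=seed)


def sample_posterior(experiment: Experiment,
                     config: FitConfig | None = None,
                     start: StructureParams | None = None,
                     x0: np.ndarray | None = None) -> PosteriorResult:
    """Posterior over the free parameters implied by the joint cost.

    The target density is exp(−χ²/2) with flat priors inside the bounds —
    the correlation-probe posterior, not a full error model.  Start from a
    fit optimum (``x0``) when available.
    """
    config = config or FitConfig()
    model = JointModel(experiment, config, start=start)

    def log_prob(x):
        try:
            return -0.5 * model.chi_square(x).total
        except FloatingPointError:
            return -np.inf

    return sample_bounded(log_prob, x0 if x0 is not None else model.x0,
                          model.lb, model.ub, n_walkers=config.n_walkers,
                          n_steps=config.n_steps, n_burn=config.n_burn,
                          seed=config.seed, names=model.names)


def correlation_map(samples, pair: tuple[str, str] | tuple[int, int],
                    bins: int = 50):
    """Normalized 2-D posterior histogram + Pearson r for a parameter pair.

    Returns ``(hist, x_edges, y_edges, pearson_r)``; the histogram is a
    probability density.  Needs ≥ 1000 draws; a constant parameter is
    flagged (correlation undefined).
    """
    if isinstance(samples, PosteriorResult):
        cols = [samples.column(p) if isinstance(p, str)
                else samples.samples[:, p] for p in pair]
    else:
        arr = np.asarray(samples, float)
        cols = [arr[:, p] for p in pair]
    a, b = cols
    if a.size < 1000:
        raise ValueError(f"need at least 1000 draws, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(f"parameter pair {pair} contains a constant; "
                         "correlation undefined")
    hist, xe, ye = np.histogram2d(a, b, bins=bins, density=True)
    r = float(np.corrcoef(a, b)[0, 1])
    return hist, xe, ye, r
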