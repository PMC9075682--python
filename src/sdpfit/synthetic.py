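"""Synthetic ground truths and noisy multi-contrast experiments.

Emulates the measured study conditions: one SAXS curve (q = 0.01–0.6 Å⁻¹)
plus up to three SANS contrasts (q = 0.01–0.3 Å⁻¹; 100/75/50% D2O) from
~100-nm extruded vesicles, with per-dataset multiplicative scale, additive
constant background and intensity-proportional Gaussian noise.  Everything
is seeded and reproducible, so every downstream stage is testable without
measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chains import MismatchRecord, chain_length
from .fitting import Dataset, Experiment, joint_model_intensities
from .forward import InstrumentSpec, VesicleSpec
from .profiles import StructureParams, template_structure
from .volumetrics import LipidSpec, SolventSpec, builtin_lipid


@dataclass(frozen=True)
class ExperimentDesign:
    """q-grids, contrasts, noise model and nuisance truths of one campaign.

    Noise: σ(q) = max(f_rel · I(q), floor), with the floor tied to the peak
    intensity so the model is scale-free.  Background truths are set to
    ``background_rel`` times the model intensity at the highest q of each
    dataset (a constant, dataset-specific offset, as produced by incoherent
    scattering after imperfect solvent subtraction).
    """

    q_xray: np.ndarray = field(
        default_factory=lambda: np.linspace(0.01, 0.6, 400))
    q_neutron: np.ndarray = field(
        default_factory=lambda: np.linspace(0.01, 0.3, 120))
    d2o_fractions: tuple[float, ...] = (1.0, 0.75, 0.5)
    noise_rel_xray: float = 0.01
    noise_rel_neutron: float = 0.03
    noise_floor_rel: float = 1e-6     # × peak intensity
    scale_xray: float = 1.0
    scale_neutron: float = 1.0
    background_rel: float = 0.2      # × model intensity at q_max
    vesicle: VesicleSpec = field(default_factory=VesicleSpec)

    def __post_init__(self) -> None:
        for grid in (self.q_xray, self.q_neutron):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("q grids must be strictly increasing")
        if min(self.noise_rel_xray, self.noise_rel_neutron,
               self.noise_floor_rel) < 0 or self.noise_floor_rel == 0:
            raise ValueError("noise levels must be >= 0 with a positive "
                             "floor (the floor keeps uncertainties > 0)")


#: fields drawn by make_truth, ±10% around the per-lipid template
_DRAWN = ("A", "z_CG", "z_PCN", "z_CholCH3", "sig_CG", "sig_PCN", "sig_CH3",
          "s_poly")


def make_truth(lipid: LipidSpec | str, seed: int,
               spread: float = 0.10, max_tries: int = 1000
               ) -> StructureParams:
    """Draw a ground-truth structure around the per-lipid template.

    Every adjustable parameter is drawn uniformly within ±``spread`` of its
    template value; draws violating the headgroup-ordering invariant are
    rejected and retried.  Reproducible per seed.
    """
    if isinstance(lipid, str):
        lipid = builtin_lipid(lipid)
    template = template_structure(lipid)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        draws = {f: getattr(template, f) * rng.uniform(1 - spread, 1 + spread)
                 for f in _DRAWN}
        params = replace(template, **draws)
        try:
            params.validate()
        except ValueError:
            continue
        return params
    raise RuntimeError("could not draw a valid structure; widen the bounds")


def simulate_experiment(truth: StructureParams, lipid: LipidSpec | str,
                        design: ExperimentDesign | None = None,
                        seed: int = 0, n_sans: int | None = None,
                        solvent: SolventSpec | None = None) -> Experiment:
    """Forward-model a joint SAXS/SANS campaign and add seeded noise.

    The returned experiment's uncertainty columns equal the generating σ(q).
    Instrument records are left at neutral values (the generating scales and
    backgrounds are stashed in ``experiment.truth_instruments``) so that a
    subsequent fit starts from the same ignorance it would face on measured
    data.
    """
    if isinstance(lipid, str):
        lipid = builtin_lipid(lipid)
    if design is None:
        design = ExperimentDesign()
    if solvent is None:
        solvent = SolventSpec()
    fractions = design.d2o_fractions[:n_sans] if n_sans is not None \
        else design.d2o_fractions
    rng = np.random.default_rng(seed)

    datasets = [Dataset(probe="xray", d2o_fraction=solvent.d2o_fraction,
                        q=np.array(design.q_xray),
                        intensity=np.zeros_like(design.q_xray),
                        sigma=np.ones_like(design.q_xray),
                        instrument=InstrumentSpec(scale=design.scale_xray))]
    for x in fractions:
        datasets.append(Dataset(
            probe="neutron", d2o_fraction=x, q=np.array(design.q_neutron),
            intensity=np.zeros_like(design.q_neutron),
            sigma=np.ones_like(design.q_neutron),
            instrument=InstrumentSpec(scale=design.scale_neutron)))
    experiment = Experiment(lipid=lipid, solvent=solvent,
                            vesicle=design.vesicle, datasets=datasets)

    clean = joint_model_intensities(truth, experiment)
    truth_instruments = []
    for ds, model in zip(experiment.datasets, clean):
        rel = design.noise_rel_xray if ds.probe == "xray" \
            else design.noise_rel_neutron
        background = design.background_rel * model[-1]
        signal = ds.instrument.scale * model + background
        noise_sigma = rel * signal
        ds.intensity = signal + rng.normal(0.0, 1.0, signal.size) \
            * noise_sigma
        ds.sigma = np.maximum(noise_sigma,
                              design.noise_floor_rel * signal.max())
        truth_instruments.append(replace(ds.instrument,
                                         background=background))
        ds.instrument = InstrumentSpec()
    experiment.truth_instruments = truth_instruments
    return experiment


def make_mismatch_dataset(k: float, sigma_sym: float, d_tilt: float,
                          chain_pairs: list[tuple], noise: float = 0.0,
                          seed: int = 0) -> list[MismatchRecord]:
    """Generate mismatch records from the linear tilt law plus noise.

    ``chain_pairs`` are ((n1, db1), (n2, db2)) tuples mapped through the
    shipped l_C table; σ_CH3 = k|l1 − l2 + d_tilt| + σ_sym + ε with
    ε ~ N(0, noise²), seeded.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, (c1, c2) in enumerate(chain_pairs):
        l1, l2 = chain_length(tuple(c1)), chain_length(tuple(c2))
        sigma = k * abs(l1 - l2 + d_tilt) + sigma_sym
        if noise > 0:
            sigma += rng.normal(0.0, noise)
        records.append(MismatchRecord(
            name=f"synthetic-{c1[0]}:{c1[1]}/{c2[0]}:{c2[1]}-{i}",
            sigma_ch3=sigma, l_sn1=l1, l_sn2=l2))
    return records
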