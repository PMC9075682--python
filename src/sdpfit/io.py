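"""Readers, writers, run configuration and the end-to-end pipeline.

Scattering curves travel as 3- or 4-column whitespace- or comma-separated
text (q [Å⁻¹], intensity, uncertainty[, σ_q]) with ``#`` comments.  A run
configuration is one YAML file; results are written as self-describing text
tables plus a JSON reproducibility manifest (config hash, seed, package
version), and posterior draws as an HDF5 table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .chains import default_records, fit_backbone_tilt, lipid_metrics
from .fitting import Dataset, Experiment, FitConfig, FitResult, fit, \
    sample_posterior
from .forward import InstrumentSpec, VesicleSpec
from .profiles import profiles_to_table
from .synthetic import ExperimentDesign, make_truth, simulate_experiment
from .volumetrics import SolventSpec, builtin_lipid

log = logging.getLogger("sdpfit")


# ---------------------------------------------------------------------------
# column-text datasets
# ---------------------------------------------------------------------------

class DatasetParseError(ValueError):
    pass


def read_dataset(path, probe: str, d2o_fraction: float = 1.0,
                 instrument: InstrumentSpec | None = None) -> Dataset:
    """Parse a column-text scattering curve, validating as it goes.

    Errors (non-numeric rows, non-monotone q, σ ≤ 0, ragged columns) name
    the offending 1-based line number.
    """
    rows, ncols = [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = re.split(r"[,\s]+", text)
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise DatasetParseError(
                    f"{path}:{lineno}: non-numeric row {text!r}") from None
            if len(values) not in (3, 4):
                raise DatasetParseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got "
                    f"{len(values)}")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise DatasetParseError(
                    f"{path}:{lineno}: ragged column count")
            if rows and values[0] <= rows[-1][0]:
                raise DatasetParseError(
                    f"{path}:{lineno}: q = {values[0]} not strictly "
                    f"increasing")
            if values[2] <= 0:
                raise DatasetParseError(
                    f"{path}:{lineno}: uncertainty {values[2]} <= 0")
            rows.append(values)
    if not rows:
        raise DatasetParseError(f"{path}: no data rows")
    arr = np.array(rows)
    return Dataset(probe=probe, d2o_fraction=d2o_fraction,
                   q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2],
                   sigma_q=arr[:, 3] if ncols == 4 else None,
                   instrument=instrument or InstrumentSpec())


def write_dataset(path, dataset: Dataset, header: str = "") -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write(f"# probe: {dataset.probe}  d2o_fraction: "
                 f"{dataset.d2o_fraction}\n")
        cols = "# q[1/A]  intensity  sigma"
        fh.write(cols + ("  sigma_q\n" if dataset.sigma_q is not None
                         else "\n"))
        for i in range(dataset.q.size):
            row = [repr(float(dataset.q[i])), repr(float(dataset.intensity[i])),
                   repr(float(dataset.sigma[i]))]
            if dataset.sigma_q is not None:
                row.append(repr(float(dataset.sigma_q[i])))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One pipeline run: lipid, datasets (or simulation), fit/MCMC settings."""

    lipid: str
    output_dir: str = "sdpfit-out"
    seed: int = 0
    datasets: list[dict] = field(default_factory=list)
    simulate: bool = False
    n_sans: int = 3
    solvent: dict = field(default_factory=dict)
    vesicle: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    mcmc: bool = False
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        builtin_lipid(cfg.lipid)  # fail early on unknown lipids
        for rec in cfg.datasets:
            if not Path(rec["path"]).exists():
                raise FileNotFoundError(f"dataset file {rec['path']} "
                                        "does not exist")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def fit_config(self) -> FitConfig:
        kw = dict(self.fit)
        kw.setdefault("seed", self.seed)
        if "free" in kw:
            kw["free"] = tuple(kw["free"])
        return FitConfig(**kw)


def _experiment_from_config(config: RunConfig) -> Experiment:
    lipid = builtin_lipid(config.lipid)
    solvent = SolventSpec(**config.solvent) if config.solvent \
        else SolventSpec()
    vesicle = VesicleSpec(**config.vesicle) if config.vesicle \
        else VesicleSpec()
    if config.simulate:
        truth = make_truth(lipid, seed=config.seed)
        exp = simulate_experiment(truth, lipid, ExperimentDesign(
            vesicle=vesicle), seed=config.seed, n_sans=config.n_sans,
            solvent=solvent)
        exp.meta_truth = truth  # kept for inspection
        return exp
    datasets = [read_dataset(rec["path"], rec["probe"],
                             rec.get("d2o_fraction", 1.0))
                for rec in config.datasets]
    return Experiment(lipid=lipid, solvent=solvent, vesicle=vesicle,
                      datasets=datasets)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def write_fit_result(path, result: FitResult) -> None:
    """Self-describing parameter table (name, value, 1σ, unit)."""
    units = {"A": "A^2", "z_CG": "A", "z_PCN": "A", "z_CholCH3": "A",
             "sig_CG": "A", "sig_PCN": "A", "sig_CH3": "A", "s_poly": "A",
             "V_BW": "A^3", "V_H": "A^3"}
    with open(path, "w") as fh:
        fh.write(f"# sdpfit {__version__} fit result\n")
        fh.write(f"# chi2_total {result.chi2.total:.8e}\n")
        fh.write(f"# chi2_xray {result.chi2.chi_xray:.8e}\n")
        fh.write(f"# chi2_neutron {result.chi2.chi_neutron:.8e}\n")
        fh.write(f"# penalty {result.chi2.penalty:.8e}\n")
        fh.write(f"# alpha {result.chi2.alpha:.8e}\n")
        fh.write(f"# converged {result.success}  nfev {result.nfev}\n")
        fh.write("name\tvalue\tstderr\tunit\n")
        for name, value, err in zip(result.names, result.x, result.perr):
            base = name.rsplit("_", 1)[0] \
                if name.startswith(("scale_", "background_")) else name
            fh.write(f"{name}\t{value:.8g}\t{err:.3g}\t"
                     f"{units.get(base, '-')}\n")
        for name, value in result.derived.items():
            fh.write(f"derived:{name}\t{value:.8g}\t-\t-\n")


def write_posterior(path, posterior) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=posterior.samples)
        fh.attrs["names"] = list(posterior.names)
        fh.attrs["acceptance_fraction"] = posterior.acceptance_fraction
        fh.attrs["n_walkers"] = posterior.n_walkers
        fh.attrs["n_steps"] = posterior.n_steps
        fh.attrs["seed"] = posterior.seed


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """fit → derived quantities → optional MCMC, with persisted artifacts.

    Every stage logs under its name and failures abort with partial outputs
    preserved.  Returns a summary dict mirroring the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(),
                                      logging.INFO))
    summary: dict = {"stages": []}

    def stage(name):
        log.info("stage: %s", name)
        summary["stages"].append(name)

    stage("load")
    experiment = _experiment_from_config(config)
    if config.simulate:
        for i, ds in enumerate(experiment.datasets):
            label = ds.probe if ds.probe == "xray" \
                else f"sans_{int(ds.d2o_fraction * 100)}"
            write_dataset(out / f"data_{label}.dat", ds,
                          header=f"simulated {config.lipid} dataset {i}")

    stage("fit")
    fit_config = config.fit_config()
    result = fit(experiment, fit_config)
    write_fit_result(out / "parameters.tsv", result)
    prof = result.model.central_profiles(result.params)
    (out / "profiles.tsv").write_text(
        profiles_to_table(prof, experiment.lipid, experiment.solvent))
    if not result.success:
        log.warning("fit did not converge: %s", result.message)

    stage("metrics")
    summary["derived"] = result.derived

    if config.mcmc:
        stage("mcmc")
        posterior = sample_posterior(experiment, fit_config, x0=result.x)
        write_posterior(out / "posterior.h5", posterior)
        summary["mcmc_acceptance"] = posterior.acceptance_fraction

    stage("manifest")
    manifest = {"config_sha256": config.digest(), "seed": config.seed,
                "version": __version__, "lipid": config.lipid,
                "chi2_total": result.chi2.total,
                "converged": result.success,
                "derived": result.derived}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    summary["manifest"] = manifest
    return summary


# ---------------------------------------------------------------------------
# chain-metric table commands (library back-ends for the CLI)
# ---------------------------------------------------------------------------

def metrics_table(table) -> "object":
    """σ_CH3⁰ and ϒ per row of a structural-parameter table.

    ``table`` is a DataFrame (or path to CSV) with columns lipid, A,
    twoD_C, sigma_CH3.
    """
    import pandas as pd
    if not hasattr(table, "iterrows"):
        table = pd.read_csv(table, comment="#")
    rows = []
    for _, row in table.iterrows():
        m = lipid_metrics(row["lipid"], float(row["A"]),
                          float(row["twoD_C"]), float(row["sigma_CH3"]))
        rows.append({"lipid": row["lipid"], **m})
    return pd.DataFrame(rows).set_index("lipid")


def tiltfit_summary(include_monounsaturated: bool = True,
                    weighted: bool = False) -> dict:
    records = default_records(include_monounsaturated)
    weights = None
    if weighted:
        weights = 1.0 / np.array([(0.05 * r.sigma_ch3) ** 2
                                  for r in records])
    res = fit_backbone_tilt(records, weights=weights)
    return {"d_tilt": res.d_tilt, "k": res.k,
            "sigma_CH3_sym": res.sigma_ch3_sym,
            "iterations": res.iterations, "converged": res.converged,
            "records": list(res.record_names)}
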