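# sdpfit

Joint SAXS/SANS refinement of fluid lipid bilayer structure with a
composition-specific scattering-density-profile (SDP) model, a headgroup
hydration shell, and hydrocarbon chain-asymmetry metrics.

## Who this is for

Membrane biophysicists analyzing small-angle X-ray and neutron scattering
from large unilamellar vesicles (LUVs, ~100 nm) of phosphatidylcholines and
sphingomyelins in the fluid phase.  The package answers two kinds of
question:

1. **Trans-bilayer structure.**  Given one SAXS curve and one or more SANS
   contrasts (100/75/50% D₂O), what are the area per lipid *A*, the Luzzati
   thickness *D*<sub>B</sub>, the hydrophobic thickness 2*D*<sub>C</sub>, the
   terminal-methyl width σ<sub>CH3</sub>, and the number of bound waters
   *n*<sub>W</sub>?
2. **Chain interdigitation.**  Across lipids with mismatched sn1/sn2 chains,
   how far do the chain termini stray from the bilayer midplane, and how
   much of that is explained by the glycerol-backbone tilt?

## The model

The bilayer is parsed into quasimolecular moieties with fixed volumes,
neutron scattering lengths and electron counts: an error-function
hydrocarbon slab (CH₂ + CH), a single midplane Gaussian holding both
terminal methyls (integral 2*V*<sub>CH3</sub>/*A*), and mirrored Gaussians
for the carbonyl-glycerol backbone, phosphate+CH₂CH₂N and choline-methyl
groups.  Water fills the remaining volume; inside an error-function shell
wrapped around the headgroup (width *d*<sub>shell</sub> = 3.1 Å) it is
*bound* water with molecular volume *V*<sub>BW</sub> = 29.3 Å³ < 30.28 Å³,
i.e. ~3% denser than bulk — which is what produces the low-*q* SAXS minimum
near *q* ≈ 0.02 Å⁻¹ for PC vesicles.

The flat-bilayer form factor is the cosine transform of the contrast
profile; a Gaussian polydispersity of the hydrocarbon half-thickness and a
Schulz-averaged thin-shell factor (separated form factor) yield the vesicle
intensity.  X-ray and neutron datasets are fit jointly with the cost

```
χ² = χ²_X + α χ²_N + (n_H2O / σ_H2O)²
```

where α equalizes q-space point densities between the probes and the last
term penalizes unit-cell overfilling ("negative water").  Point estimates
use bounded trust-region-reflective least squares; parameter correlations
come from a seeded ensemble MCMC targeting exp(−χ²/2) with flat priors.

Chain asymmetry is quantified by

* σ<sub>CH3</sub>⁰ = 2*V*<sub>CH3</sub>/(√(2π)·*A*) — the no-overlap methyl
  width (volume probability reaches 1 at the midplane),
* ϒ = (σ<sub>CH3</sub> − σ<sub>CH3</sub>⁰)/(*D*<sub>C</sub>/3 −
  σ<sub>CH3</sub>⁰) — relative methyl overlap between 0 (no overlap) and 1
  (methyls smeared over the whole chain region),
* the backbone-tilt regression σ<sub>CH3</sub> = *k*·|Δ*l*<sub>C</sub> +
  *d*<sub>tilt</sub>| + σ<sub>CH3</sub><sup>sym</sup>, solved by alternating
  ordinary least squares with a 1-D search over *d*<sub>tilt</sub>.

Units package-wide: Å, Å⁻¹, Å², Å³, fm (neutron scattering lengths),
e⁻ (electron counts).

## Worked example

`python examples/03_chain_metrics.py` prints:

```
lipid     A [Å²]  2D_C [Å] σ_CH3 [Å] σ_CH3⁰ [Å]      ϒ
DPPC        63.1      28.6      2.91       1.42   0.45
MSPC        62.2      29.1      3.34       1.44   0.56
SMPC        62.0      29.2      3.67       1.45   0.65
PMPC        62.9      27.0      3.12       1.43   0.55
POPC        67.5      28.4      3.41       1.33   0.61
SOPC        68.8      29.2      3.31       1.30   0.56
MSM         64.8      32.8      4.29       1.38   0.71

backbone-tilt regression over 7 lipids (2 alternations, converged=True):
  d_tilt      = 0.496 Å  (sn1 penetrates deeper)
  slope k     = 0.197        (overlap per Å of mismatch)
  σ_CH3^sym   = 2.801 Å (chain-symmetric limit)
```

Reading: ϒ grows from 0.45 (chain-symmetric DPPC) to 0.71 for milk
sphingomyelin — the most chain-asymmetric lipid smears its methyls over
~70% of the hydrocarbon half-thickness.  The tilt offset of ~0.5 Å means
the sn1 chain effectively reaches half a CH₂ group deeper than sn2, so the
positional isomers MSPC (14:0/18:0) and SMPC (18:0/14:0) are *not*
equivalent: SMPC's mismatch is enlarged, MSPC's partly cancelled, matching
σ<sub>CH3</sub> = 3.67 Å vs 3.34 Å.

The other examples: `01_bilayer_profiles.py` (profiles and derived
thicknesses), `02_simulate_and_fit.py` (synthetic joint campaign and
parameter recovery), `04_posterior_correlations.py` (MCMC correlation
ridges).  A thin CLI mirrors the library: `sdpfit simulate|fit|mcmc|
predict|metrics|tiltfit` (see `sdpfit --help`); run configurations are
single YAML files, scattering curves 3/4-column text (q, I, σ[, σ_q]).

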