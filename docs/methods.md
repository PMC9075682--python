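# Methods

This note documents the model, its numerical realization, the synthetic
data the tests rely on, and the design choices made where the problem was
genuinely open.  Everything quantitative stated here is computed by the
test suite or the examples; nothing is quoted from elsewhere.

## The scattering-density-profile model

One bilayer unit cell holds two lipids (one per leaflet) on an area *A*.
Moiety volume probabilities on a symmetric z-grid (spacing 0.1 Å):

* **Hydrocarbon slab** (methylenes + methines): error-function pair of
  half-width *D*<sub>C</sub> = *V*<sub>HC</sub>/*A* and fixed smearing
  σ<sub>CH2</sub> = 2.5 Å.
* **Terminal methyls**: a single midplane Gaussian of width σ<sub>CH3</sub>
  and integral 2*V*<sub>CH3</sub>/*A*, shared by both leaflets.  This makes
  the no-overlap condition exact: the probability peaks at 1 exactly when
  σ<sub>CH3</sub> = σ<sub>CH3</sub>⁰ = 2*V*<sub>CH3</sub>/(√(2π)*A*).
  The methyl part is subtracted from the slab.
* **Headgroup** (carbonyl-glycerol CG, phosphate+CH₂CH₂N PCN, choline
  methyls CholCH3): mirrored Gaussian pairs with integrals 2*V*<sub>i</sub>/*A*;
  σ<sub>CholCH3</sub> = 3 Å is fixed, σ<sub>CG</sub>, σ<sub>PCN</sub> adjust.
* **Methines** (one per double-bond carbon) carry no Gaussian of their own:
  they are folded into the slab and enter the scattering density through
  the volume-weighted joint (CH₂+CH) density.  This removes one poorly
  determined volume ratio from the adjustable set.
* **Water** fills 1 − Σpᵢ wherever that is positive.  Overfilled cells are
  *not* rejected: the excess integrates to the "negative water" count
  n_H2O = (A/V_W)·∫max(Σpᵢ−1, 0)dz, which the fit penalizes (soft barrier)
  rather than forbids, so optimizers can traverse shallow overfills.

**Hydration shell.**  Between the hydrocarbon edge *D*<sub>C</sub> and an
outer boundary the water is "bound": same molecular scattering power,
smaller molecular volume *V*<sub>BW</sub> ≤ *V*<sub>W</sub> = 30.28 Å³, so
its density is the bulk value × *V*<sub>W</sub>/*V*<sub>BW</sub> (~3% high
at the default 29.3 Å³).  The shell region is an error-function annulus
with the σ<sub>CH2</sub> smearing.  Two outer-boundary conventions are
implemented, because "up to the choline position plus its width" and "a
3.1 Å wide layer around the headgroup" differ in where the 3.1 Å is added:
the default `choline_plus_shell` uses z<sub>CholCH3</sub> + σ<sub>CholCH3</sub>
+ d<sub>shell</sub>; `choline` stops at z<sub>CholCH3</sub> + σ<sub>CholCH3</sub>.
Setting *V*<sub>BW</sub> = *V*<sub>W</sub> switches the shell off exactly.

**Derived quantities.** D_B = ∫(1−p_W)dz (equals 2V_L/A whenever nothing
overfills and the grid contains the lipid); n_W = (A/V_BW)·∫ p_W dz over
|z| < D_B/2 (both leaflets of the two-lipid cell, i.e. the per-lipid
convention of the model).  n_W is sensitive to the shell-boundary reading
and to headgroup placement; it should be quoted with generous uncertainty.

## Volumetric constants

Moiety volumes are fixed, not fitted, to keep σ<sub>CH3</sub> comparable
across lipids: V_H = 328 Å³ for the PC headgroup (CG 147, PCN 90, CholCH3
91), methylene 28.1 Å³, methyl/methylene ratio r = 2.0 (total terminal-
methyl volume 112.4 Å³ per lipid), methine/methylene r₁₂ = 0.91 — a
fluid-phase 50 °C set consistent with σ<sub>CH3</sub>⁰ ≈ 1.4 Å at A ≈ 63 Å²
and with the tabulated hydrophobic thicknesses to ~1%.  They live in an
editable YAML registry (`sdpfit/data/lipids.yaml`) so alternative volume
sets can be swapped without code changes.  Milk sphingomyelin is collapsed
to its average acyl composition (22:0 on a d18:1 base); its backbone moiety
(sphingosine C1–C3, amide, NH+OH) plays the CG role and carries the only
two exchangeable hydrogens in the registry, interpolated linearly in the
D₂O fraction.

## Forward model

* **Flat-bilayer amplitude**: trapezoid cosine transform of Δρ(z) on the
  0.1 Å grid.  For profiles made of Gaussians and error-function slabs this
  is accurate to ~10⁻¹⁵ relative (spectral accuracy of the trapezoid rule
  for smooth decaying integrands), verified against the closed forms.
* **Thickness polydispersity**: Gauss–Hermite average (11 nodes by default)
  of |F|² over a Gaussian distribution of *D*<sub>C</sub> with width
  s_poly; only the slab half-width varies, the headgroup Gaussians and the
  shell ride rigidly on the moving hydrocarbon edge.  Nodes pushing
  *D*<sub>C</sub> below 1 Å are dropped and the weights renormalized;
  s_poly ≥ *D*<sub>C</sub>/3 is rejected as unphysical.
* **Vesicle shape**: separated form factor — a thin-shell factor
  ⟨(4πR² sin(qR)/(qR))²⟩ multiplies the bilayer intensity.  The Schulz
  (gamma) radius average is evaluated in closed form via the gamma
  characteristic function (⟨R²cos 2qR⟩ analytic), which is exact for every
  polydispersity; naive node-based quadrature undersamples sin(qR) at
  q·R̄ of several hundred, which is why the closed form is used in the
  model and quadrature only as a test oracle.  Defaults R̄ = 550 Å,
  polydispersity 0.25 (typical 100-nm extrusion); the factor is normalized
  to 1 at q→0 so intensities stay on the bilayer scale.
* **Instrument**: per-dataset multiplicative scale and additive constant
  background (negative backgrounds allowed — solvent over-subtraction);
  optional Gaussian q-smearing from a σ_q column or a Δq/q = 10% width,
  off by default.

## Joint fitting

χ² = χ²_X + α·χ²_N + (n_H2O/σ_H2O)², with α the ratio of q-space point
densities (X-ray over neutron), divided by the number of neutron contrasts;
per-dataset neutron densities are averaged by default (a pooled-range
variant is available).  Default σ_H2O = 0.1 molecules, making a tenth of a
spurious water cost χ² = 1 — a soft barrier that in practice drives
n_H2O → 0 without trapping the optimizer.

Free by default: A, the three headgroup positions, σ_CG, σ_PCN, σ_CH3,
s_poly, and per-dataset scale/background; optionally V_BW and the headgroup
volume V_H (volumes rescaled jointly, scattering lengths untouched).
Bounds: A ∈ [45, 90] Å², positions ∈ [5, 35] Å, σ ∈ [1.5, 6] Å — generous
physical ranges.  Optimization is bounded trust-region-reflective least
squares on the residual vector (neutron rows scaled by √α, the penalty as
one extra row), deterministic given starts.  1σ uncertainties come from
the SVD of the column-normalized jacobian at the optimum.

**MCMC.**  The correlation analysis targets exp(−χ²/2) with flat priors
inside the bounds — a correlation probe, not a calibrated error model —
using the seeded affine-invariant ensemble sampler (emcee), which is
asymptotically exact for this target.  Correlation maps report the
normalized 2-D histogram and Pearson r.  Two caveats from the synthetic
studies: (i) marginal correlations depend on what else is free — the
z_CG–z_PCN ridge is sharp when the headgroup pair is probed around the
optimum, diluted when all twelve parameters float; (ii) the strong ridges
are *compensation* ridges (converged chains give r ≈ −1 for z_CG–z_PCN
and V_BW–V_H): the data constrain the composite headgroup peak and the
headgroup-region density, so the members of each pair trade off against
one another.  Short, unconverged chains can show either sign — check the
autocorrelation time before reading a map.

## Chain-asymmetry analysis

Chain hydrophobic lengths l_C are equated to the half hydrophobic
thickness of the matching chain-symmetric fluid bilayer and shipped as an
editable table: l_C(n) = 14.3 + 0.9(n−16) Å for saturated acyls (anchored
at the dipalmitoyl value, 0.9 Å per methylene), oleoyl 13.0 Å (the
stearoyl-oleoyl thickness minus the stearoyl value — the cis kink shortens
the effective length), sphingosine-effective 12.0 Å (C4–C18 segment, whose
first two carbons form a trans double bond).  The tilt regression
alternates OLS of σ_CH3 on |Δl_C + d_tilt| with a bounded scalar
minimization of the profiled residual over d_tilt ∈ [−2, 2] Å (tolerance
10⁻⁸ Å, ≤200 alternations); it is invariant to record order and flips
d_tilt's sign under a global sn1↔sn2 relabeling.  The default record set
is all seven studied lipids (four saturated PCs, two monounsaturated PCs,
milk sphingomyelin); a flag restricts to the saturated+sphingomyelin
subset.  Records can be weighted by their σ_CH3 uncertainties; the default
is unweighted.

## Synthetic data

The generator emulates the measured campaign: SAXS q = 0.01–0.6 Å⁻¹ (400
points), SANS q = 0.01–0.3 Å⁻¹ (120 points) at 100/75/50% D₂O, ~100-nm
vesicles.  Noise is Gaussian with σ(q) = rel·I(q) (1% SAXS, 3% SANS by
default) over a small positive floor; backgrounds are set to 20% of the
model intensity at each dataset's q_max, scales to 1.  Ground truths are
drawn uniformly within ±10% of per-lipid templates (areas and methyl
widths from the shipped reference table, headgroup positions placed
geometrically off the hydrocarbon edge); draws violating the headgroup
ordering are rejected.  Everything is seeded.

What the generator does *not* emulate: instrument resolution smearing
(available but off), inter-vesicle structure factors (dilute limit),
multilamellarity, leaflet asymmetry, and any mismatch between the model
family and reality — synthetic recovery tests therefore demonstrate
estimator correctness and identifiability, not accuracy on measured
curves.

## Numerical choices and degenerate inputs

Grid |z| ≤ 50 Å at 0.1 Å during fits (headgroup + shell + ≥15 Å of bulk;
a short grid raises an extent error).  Unit-cell closure and moiety
normalization hold to 10⁻⁹/10⁻⁶.  The polydispersity→0, shell-off
(V_BW = V_W), and monodisperse-vesicle limits reduce exactly to their
simple counterparts.  The separated form factor misplaces the sharp shell
nulls by O((t/R)²), so pointwise comparisons against the exact core-shell
sphere exclude the null neighborhoods.  Degenerate tilt designs (all
mismatches equal, <3 records) and degenerate overlap scales
(D_C/3 ≤ σ_CH3⁰) raise explicit errors.

## Known limitations

* Symmetric bilayers only; no gel phase, no leaflet asymmetry.
* n_W (and to a lesser degree D_B) depend on the shell-boundary convention;
  compare only within one convention.
* The thickness-polydispersity average improves but does not perfectly
  reproduce measured form-factor minima depths (peristaltic modes are not
  wavelength-uniform); no further correction is attempted.
* The backbone-tilt fit is a regression on fitted σ_CH3 values, not a
  direct scattering observable; its value inherits the l_C table's
  conventions for unsaturated and sphingoid chains.
* Scattering cannot distinguish interdigitation from chain back-bending;
  ϒ measures methyl dislocation, whatever its origin.
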