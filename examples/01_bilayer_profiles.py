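"""Build the trans-bilayer profile of fluid DPPC and its derived thicknesses.

The bilayer is parsed into quasimolecular moieties (hydrocarbon slab,
midplane terminal-methyl Gaussian, three headgroup Gaussians) plus a
hydration shell of denser water around the headgroup.  The script prints the
thicknesses and hydration numbers the profile implies.
"""

import sdpfit as s

lipid = s.builtin_lipid("DPPC")
solvent = s.SolventSpec()              # 100% D2O, V_BW = 29.3 Å³
params = s.template_structure(lipid)   # A = 63.1 Å², fluid phase, 50 °C

profiles = s.build_profiles(params, lipid, solvent)

print(f"lipid                 : {lipid.name}")
print(f"area per lipid A      : {params.A:.1f} Å²")
print(f"hydrophobic 2D_C      : {2 * params.D_C(lipid):.2f} Å")
print(f"Luzzati thickness D_B : {s.luzzati_thickness(profiles):.2f} Å "
      f"(= 2 V_L/A = {2 * lipid.V_L / params.A:.2f} Å)")
print(f"bound waters n_W      : {s.bound_water_count(profiles, solvent):.1f}"
      f" per lipid")
print(f"negative water n_H2O  : {s.negative_water(profiles, solvent):.3f} "
      f"(0 = nothing overfills)")

s0 = s.sigma_ch3_zero(params.A, lipid.V_CH3)
print(f"minimal methyl width  : {s0:.2f} Å (peak-height condition)")
print(f"methyl overlap ϒ      : "
      f"{s.upsilon(params.sig_CH3, params.D_C(lipid), s0):.2f} "
      f"(0 = no overlap, 1 = smeared over the chain region)")
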