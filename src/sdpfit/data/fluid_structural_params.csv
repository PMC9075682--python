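# Reference trans-bilayer structural parameters of fluid-phase bilayers at
# 50 degC from joint SAXS/SANS refinements of ~100-nm extruded vesicles.
# Columns: area per lipid A [A^2] (rel. unc. 2%), Luzzati thickness D_B [A]
# (5%), hydrophobic thickness twoD_C [A] (3%), terminal-methyl Gaussian width
# sigma_CH3 [A] (5%), bound waters per lipid n_W (10%), relative methyl
# overlap upsilon [-] (7%).
lipid,A,D_B,twoD_C,sigma_CH3,n_W,upsilon
DPPC,63.1,40.3,28.6,2.91,9.7,0.43
MSPC,62.2,40.3,29.1,3.34,11.3,0.55
SMPC,62.0,40.3,29.2,3.67,12.8,0.65
PMPC,62.9,38.4,27.0,3.12,12.1,0.54
POPC,67.5,38.4,28.4,3.41,16.6,0.60
SOPC,68.8,39.4,29.2,3.31,15.1,0.55
MSM,64.8,42.1,32.8,4.29,9.6,0.71
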