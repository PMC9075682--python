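# Hydrophobic chain lengths l_C [A] for fluid-phase hydrocarbon chains at
# 50 degC, equated to the half hydrophobic thickness D_C of the matching
# chain-symmetric bilayer.  Saturated acyls follow l_C(n) = 14.3 + 0.9 (n-16)
# (anchored at the dipalmitoyl value, 0.9 A per methylene in the fluid
# phase).  The oleoyl entry is the stearoyl-oleoyl hydrophobic thickness
# minus the stearoyl value (the cis double-bond kink shortens the effective
# length); the sphingosine entry is the effective length of the C4-C18
# segment of the d18:1 base, whose first two carbons form a trans double
# bond.  Editable: rows are "chain label, l_C".
chain,l_C
12:0,10.7
14:0,12.5
16:0,14.3
18:0,16.1
20:0,17.9
22:0,19.7
24:0,21.5
18:1,13.0
d18:1,12.0
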