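# Registry of composition-specific SDP constants for fluid-phase lipids at
# 50 °C.  Moiety volumes follow published volumetric parameter sets for
# phosphatidylcholines (headgroup volume fixed at V_H = 328 Å^3; methylene
# volume 28.1 Å^3, methyl/methylene ratio r = 2.0, methine/methylene ratio
# r12 = 0.91, consistent with σ_CH3^0 ≈ 1.4 Å at A ≈ 63 Å^2).
#
# Per-lipid moiety records aggregate ALL copies of the moiety in one lipid:
#   volume     [Å^3 per lipid]
#   b          [fm per lipid]  neutron scattering length, non-exchangeable part
#   electrons  [e- per lipid]
#   n_exch     exchangeable hydrogens (scattering length interpolates with the
#              D2O fraction of the solvent)
#
# Moiety roles: CG  = carbonyl-glycerol backbone (amide backbone for
# sphingolipids), PCN = phosphate + CH2CH2N, CholCH3 = choline methyls,
# CH2 = methylenes (error-function slab), CH = methines (folded into the
# slab), CH3 = terminal methyls (midplane Gaussian).

constants:
  V_W: 30.28        # bulk water molecular volume [Å^3]
  V_BW: 29.3        # bound (hydration-shell) water molecular volume [Å^3]
  d_shell: 3.1      # hydration-shell width [Å]
  b_H: -3.739       # [fm]
  b_D: 6.671        # [fm]
  b_O: 5.803        # [fm]

lipids:
  DPPC:
    backbone: glycerophospholipid
    chains: {sn1: [16, 0], sn2: [16, 0]}
    V_L: 1227.2
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 786.8, b: -23.296, electrons: 224, n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  DMPC:
    backbone: glycerophospholipid
    chains: {sn1: [14, 0], sn2: [14, 0]}
    V_L: 1114.8
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 674.4, b: -19.968, electrons: 192, n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  MSPC:
    backbone: glycerophospholipid
    chains: {sn1: [14, 0], sn2: [18, 0]}
    V_L: 1227.2
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 786.8, b: -23.296, electrons: 224, n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  SMPC:
    backbone: glycerophospholipid
    chains: {sn1: [18, 0], sn2: [14, 0]}
    V_L: 1227.2
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 786.8, b: -23.296, electrons: 224, n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  PMPC:
    backbone: glycerophospholipid
    chains: {sn1: [16, 0], sn2: [14, 0]}
    V_L: 1171.0
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 730.6, b: -21.632, electrons: 208, n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  POPC:
    backbone: glycerophospholipid
    chains: {sn1: [16, 0], sn2: [18, 1]}
    V_L: 1278.4
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 786.8, b: -23.296, electrons: 224, n_exch: 0}
      CH:      {volume: 51.2,  b: 5.814,   electrons: 14,  n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  SOPC:
    backbone: glycerophospholipid
    chains: {sn1: [18, 0], sn2: [18, 1]}
    V_L: 1334.6
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 37.747,  electrons: 67,  n_exch: 0}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 843.0, b: -24.960, electrons: 240, n_exch: 0}
      CH:      {volume: 51.2,  b: 5.814,   electrons: 14,  n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
  # Milk sphingomyelin collapsed to its average acyl composition: 22:0 amide-
  # linked acyl on a d18:1 sphingosine base.  The backbone moiety (sphingosine
  # C1-C3, amide C=O, NH, OH) plays the CG role; its two labile hydrogens
  # (amide NH, hydroxyl OH) exchange with solvent.
  MSM:
    backbone: sphingolipid
    chains: {sn1: [18, 1], sn2: [22, 0]}
    V_L: 1390.8
    V_H: 328.0
    moieties:
      CG:      {volume: 147.0, b: 32.594,  electrons: 53,  n_exch: 2}
      PCN:     {volume: 90.0,  b: 36.038,  electrons: 70,  n_exch: 0}
      CholCH3: {volume: 91.0,  b: -13.713, electrons: 27,  n_exch: 0}
      CH2:     {volume: 899.2, b: -26.624, electrons: 256, n_exch: 0}
      CH:      {volume: 51.2,  b: 5.814,   electrons: 14,  n_exch: 0}
      CH3:     {volume: 112.4, b: -9.142,  electrons: 18,  n_exch: 0}
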