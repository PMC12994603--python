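# Default drug model: imipramine in chloride/phosphate media.
# Constants are on the concentration scale at I_ref = 0.15 mol/L.
constants:
  pKa: 9.52
  pKw: 13.764
  pKa1_H3PO4: 1.95
  pKa2_H3PO4: 6.74
  pKa3_H3PO4: 11.60
  logK310: 8.728
  logK750: 9.970
  logK141: 0.374
solids:
  pS0: 4.602
  pKsp_BHCl: 2.338
  pKsp_BHH2PO4: 2.823
  pKsp_BH2HPO4: 6.812
sd:
  logK310: 0.0017
  logK750: 0.0040
  logK141: 0.016
  pS0: 0.02
  pKsp_BHCl: 0.02
  pKsp_BHH2PO4: 0.00010
  pKsp_BH2HPO4: 0.00009
fixed:
  - pKa
  - pKw
  - pKa1_H3PO4
  - pKa2_H3PO4
  - pKa3_H3PO4
electrode:
  alpha: 0.0
  ks: 1.0
  jH: 0.0
  jOH: 0.0
  pKw: 13.764
activity:
  form: davies
  A_DH: 0.509
  Ks_neutral: 0.42
  I_ref: 0.15
recipes:
  # weighed solid (g) per volume (mL) in a background electrolyte;
  # totals are derived from runtime molar masses.
  set1_2:
    mass_g: 0.057
    volume_mL: 1.0
    starting_material: salt_BHCl
    background_NaH2PO4: 0.14
    c_strong_acid: 0.049
  set3:
    mass_g: 0.052
    volume_mL: 1.0
    starting_material: salt_BHCl
    background_NaCl: 0.15
  set4:
    mass_g: 0.068
    volume_mL: 1.0
    starting_material: free_base
    background_NaH2PO4: 1.69
    c_strong_base: 0.46
  set5:
    mass_g: 0.071
    volume_mL: 1.0
    starting_material: free_base
    background_NaCl: 1.70
  set6:
    mass_g: 0.069
    volume_mL: 1.0
    starting_material: free_base
    background_NaH2PO4: 1.4
    background_H3PO4: 0.6
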