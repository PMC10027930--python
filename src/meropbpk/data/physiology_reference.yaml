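# Reference adult male physiology (30 y, 176 cm, 73 kg).
#
# Organ volumes and cardiac-output fractions follow standard reference-male
# compilations (ICRP-style reference man); plasma flows are derived as
# fraction x cardiac output x (1 - hematocrit).  The eGFR of this
# individual defines the normal value against which renal secretion is
# scaled in chronic kidney disease.
body_weight_kg: 73.0
height_cm: 176.0
hematocrit: 0.45
cardiac_output_blood_l_min: 6.5
egfr_ml_min_1_73: 106.78

organ_volumes_l:
  lung: 0.50
  heart: 0.33
  brain: 1.45
  muscle: 29.0
  adipose: 14.5
  skin: 3.40
  bone: 10.5
  liver: 1.80
  gut: 1.65
  spleen: 0.19
  rest: 6.00

# kidney represented mechanistically by three sub-volumes
kidney_subvolumes_l:
  plasma: 0.030
  proximal_tubule_cell: 0.150
  tubular_lumen: 0.020

venous_plasma_l: 2.00
arterial_plasma_l: 0.915

# fractions of cardiac output (sum to 1; lung perfused in series)
flow_fractions:
  heart: 0.040
  brain: 0.120
  muscle: 0.170
  adipose: 0.050
  skin: 0.050
  bone: 0.050
  liver: 0.065
  gut: 0.150
  spleen: 0.030
  kidney: 0.190
  rest: 0.085
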