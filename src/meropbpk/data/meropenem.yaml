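# Meropenem PBPK input parameters.
#
# Physicochemistry, plasma binding and renal Michaelis-Menten kinetics of
# meropenem.  Km values carry explicit concentration units and are
# normalized to µmol/L on load.  Vmax values are µmol/L/min referenced to
# the per-process effective reference volume below: the product
# vmax * reference_volume_l is the maximal amount rate (µmol/min), and
# vmax * reference_volume_l / km the linear-range intrinsic clearance.
# The reference volumes absorb tissue-expression scaling of the source
# Vmax convention; Vmax values themselves are the calibration handles.
drug:
  name: meropenem
  molecular_weight_g_mol: 383.46
  pka_acid: 3.47
  pka_base: 9.39
  logp: 1.25
  water_solubility_mg_ml: 5.63
  fu: 0.98
  binding_partner: albumin
  gfr_fraction: 1.00

processes:
  - name: DPEP1
    km: 3.56 mM
    vmax_umol_l_min: 79.34
    direction: metabolism_intracellular
    reference_volume_l: 0.47
  - name: OAT3
    km: 847 uM
    vmax_umol_l_min: 18156.72
    direction: uptake_basolateral
    reference_volume_l: 0.0065
  - name: NPT1
    km: 755.89 uM
    vmax_umol_l_min: 57.64
    direction: efflux_apical
    reference_volume_l: 0.47
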