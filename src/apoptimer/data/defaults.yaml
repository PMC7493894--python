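# Calibrated default parameterisation (uM, min).  Produced by the package's
# own calibration pipeline (scripts in the repo regenerate it): SPR-derived
# bounds on primary/secondary PC9 and C9 apoptosome binding, trained on the
# Boltzmann-shaped HeLa substrate-cleavage curve and reconstituted-apoptosome
# timer-decay points with equal weighting.
parameters:
  k_assembly: 0.1
  katp_uM: 100.0
  kon_primary: 3.99891
  koff_primary: 0.713738
  kon_secondary: 591.763
  koff_secondary: 0.0399398
  k_auto: 0.0732333
  kon_c9: 0.443868
  koff_c9: 2.82142
  k_pc9: 1.2838
  k_c9: 0.0737919
  k_devd: 2.0
  kon_xiap_c3: 150.0
  koff_xiap_c3: 0.07
  kon_xiap_c9: 100.0
  koff_xiap_c9: 1.2
  kon_smac_xiap: 240.0
  koff_smac_xiap: 0.1

# HeLa-like baseline (uM); CytC and ATP fixed at 10 and 920 uM.
initial_state:
  cytc_mito: 10.0
  smac_mito: 1.0
  apaf1: 0.4
  pc9: 0.04
  pc3: 0.2
  xiap: 0.3
  substrate: 1.0
  atp: 920.0

# Physiological concentration ranges (uM) sampled by the screens.
ranges:
  apaf1: [0.05, 1.0]
  pc9: [0.0005, 0.04]
  pc3: [0.02, 2.0]
  xiap: [0.02, 1.0]
  smac: [0.02, 1.0]

# Synthetic SPR anchor kinetics (KD uM, half-life min); stand-ins for
# figure-digitized dissociation data, used to bound the calibration.
spr_anchors:
  PC9-TM:     {kd: 0.05, t_half: 1.0}
  PC9-F404D:  {kd: 0.5,  t_half: 0.3333333}
  C9-35-12:   {kd: 5.0,  t_half: 0.1666667}
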