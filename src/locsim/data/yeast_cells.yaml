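# Two-shell yeast cell parameterization (cytoplasm core + plasma membrane +
# cell wall) for a 3 um cell at 5 MHz, plus the suspension medium.
#
# Layer values start from the standard yeast multi-shell literature set
# (membrane thickness 8 nm, wall 0.22/0.25 um) and are calibrated so the
# homogenized sphere reproduces the reference effective properties at 5 MHz:
#   viable:     eps_eff = 199.94, sigma_eff = 0.36  S/m
#   non-viable: eps_eff = 18.82,  sigma_eff = 0.013 S/m
# and, with the medium below, Clausius-Mossotti real parts of about
# +0.945 (viable) and -0.25 (non-viable).
frequency_Hz: 5.0e+6
medium:
  eps_m: 80.0
  sigma_S_per_m: 7.85628e-4
viable:
  layers:
    - {name: cytoplasm, radius_um: 2.772, eps_r: 60.0, sigma_S_per_m: 0.17101228}
    - {name: membrane, radius_um: 2.780, eps_r: 6.0, sigma_S_per_m: 2.5e-7}
    - {name: wall, radius_um: 3.000, eps_r: 60.0, sigma_S_per_m: 1.53575898}
nonviable:
  layers:
    - {name: cytoplasm, radius_um: 2.742, eps_r: 5.07219119, sigma_S_per_m: 0.01468060}
    - {name: membrane, radius_um: 2.750, eps_r: 6.0, sigma_S_per_m: 1.6e-4}
    - {name: wall, radius_um: 3.000, eps_r: 60.0, sigma_S_per_m: 1.5e-3}
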