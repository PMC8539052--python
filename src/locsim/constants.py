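"""Physical constants (CODATA 2018 exact values where defined)."""

#: Boltzmann constant, J/K
KB = 1.380649e-23

#: Vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: Standard gravitational acceleration, m/s^2
G = 9.80665
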