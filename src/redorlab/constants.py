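"""Physical constants (CODATA 2018) and gyromagnetic ratios."""

MU_0 = 1.25663706212e-6  # vacuum permeability, N A^-2
HBAR = 1.054571817e-34  # reduced Planck constant, J s

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA_1H = 2.6752218744e8
GAMMA_19F = 2.51815e8
GAMMA_15N = -2.71261804e7
GAMMA_13C = 6.728284e7

GAMMA = {"1H": GAMMA_1H, "19F": GAMMA_19F, "15N": GAMMA_15N, "13C": GAMMA_13C}
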