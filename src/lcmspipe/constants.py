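"""Physical constants used in mass arithmetic (CODATA / IUPAC values, Da)."""

#: mass of a proton; m/z shift of the M+H adduct
PROTON_MASS = 1.007276466

#: 13C - 12C mass difference; isotopologue spacing per charge
ISOTOPE_SPACING = 1.0033548

#: Na+ (sodium atom minus one electron); m/z shift of the M+Na adduct
SODIUM_CATION_MASS = 22.989218

#: K+ (potassium atom minus one electron); m/z shift of the M+K adduct
POTASSIUM_CATION_MASS = 38.963158

#: electron mass
ELECTRON_MASS = 0.000548579909
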