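"""Physical constants shared across the package.

All masses are monoisotopic and expressed in unified atomic mass units (Da).
"""

#: Elements supported in molecular formulas, in parsing alphabet order.
ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Canonical element order used when writing formula strings.
FORMULA_ORDER = ("C", "H", "O", "N", "S", "P")

#: Monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

#: Kendrick base units: name -> (nominal mass, exact monoisotopic mass).
KENDRICK_BASES = {
    "CH2": (14, 14.01565),
    "CO2": (44, 43.98983),
    "O2": (32, 31.98983),
    "CHO": (29, 29.00274),
}

#: Cox Gibbs free energy of the carbon oxidation half reaction (kJ per mol C):
#: gibbs = GIBBS_INTERCEPT + GIBBS_SLOPE * NOSC.  Configurable because different
#: standard-state conventions exist in the literature.
GIBBS_INTERCEPT = 60.3
GIBBS_SLOPE = -28.5

#: Default covalences used in the double-bond-equivalent calculation.
#: O and S have valence 2 and therefore contribute nothing to DBE.
DEFAULT_VALENCES = {"C": 4, "H": 1, "N": 3, "O": 2, "S": 2, "P": 3}
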