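"""Physical constants (CODATA 2018) and unit conversions."""

#: Boltzmann constant, J/K (exact, SI 2019).
K_B = 1.380649e-23

#: Speed of light in vacuum, m/s (exact).
C_LIGHT = 299_792_458.0

#: Unified atomic mass unit, kg/Da.
ATOMIC_MASS_KG = 1.66053906660e-27

#: FWHM of a Gaussian divided by its standard deviation: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.3548200450309493

#: Averagine stoichiometry (Senko's "average amino-acid residue"),
#: atoms of each element per averagine unit.
AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
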