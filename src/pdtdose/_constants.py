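"""Physical constants and molecular parameters used across the package.

CODATA 2018 values for h and c; standard atomic/molecular weights.
"""

PLANCK_J_S = 6.62607015e-34      # Planck constant [J s] (exact, SI 2019)
C_M_S = 2.99792458e8             # speed of light in vacuum [m s^-1] (exact)
AVOGADRO = 6.02214076e23         # [mol^-1] (exact)
LN10 = 2.302585092994046

# Ruthenium: standard atomic weight vs the 101Ru isotope actually quantified
# by ICP-MS.  The two differ by 0.16%; the standard weight is the default.
RU_ATOMIC_WEIGHT = 101.07        # [g/mol]
RU101_ISOTOPE_MASS = 100.906     # [g/mol]

TLD1433_MW = 1007.0              # [g/mol] ruthenium complex in Rutherrin
PPIX_MW = 562.66                 # [g/mol] protoporphyrin IX

# Soft tissue mass density assumed when converting ug drug per g tissue
# into molar concentration.
TISSUE_DENSITY_G_PER_ML = 1.0
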