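"""Pinned physical-constants ledger (CODATA 2018).

Every module converts energies through the factors defined here so that all
routes through the code agree bit-for-bit.  Energy conversions are routed
through kcal/mol as the hub unit.
"""

# SI defining constants (CODATA 2018, exact)
PLANCK_J_S = 6.62607015e-34          # h, J s
BOLTZMANN_J_K = 1.380649e-23         # k_B, J/K
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # c, cm/s
AVOGADRO = 6.02214076e23             # N_A, 1/mol
AMU_KG = 1.66053906660e-27           # atomic mass unit, kg

# Pinned conversion ledger
HARTREE_TO_KCAL = 627.5095           # 1 Hartree in kcal/mol
KCAL_TO_CM = 349.755                 # 1 kcal/mol in cm^-1
KCAL_TO_KJ = 4.184                   # thermochemical calorie
CM_TO_K = PLANCK_J_S * SPEED_OF_LIGHT_CM_S / BOLTZMANN_J_K  # hc/k_B, K per cm^-1

# Gas constant in the units the thermo tables use
R_KCAL = BOLTZMANN_J_K * AVOGADRO / (KCAL_TO_KJ * 1000.0)   # kcal/mol/K
R_CAL = R_KCAL * 1000.0                                     # cal/mol/K

# k_B T / h at 298.15 K is ~6.21e12 s^-1; the prefactor used by TST
KB_OVER_H = BOLTZMANN_J_K / PLANCK_J_S                      # s^-1 K^-1

# Speed of light in cm/s times h gives J per cm^-1
CM_TO_J = PLANCK_J_S * SPEED_OF_LIGHT_CM_S                  # J per cm^-1

STANDARD_PRESSURE_PA = 101325.0      # 1 atm, for the ideal-gas standard state
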