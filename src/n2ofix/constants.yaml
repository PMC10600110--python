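# Physical and thermodynamic constants used by n2ofix.
#
# Solubility sources (freshwater limit, salinity = 0):
#   N2, Ar : Hamme & Emerson (2004) Deep-Sea Res. I 51, 1517-1528.
#            ln C = A0 + A1*Ts + A2*Ts^2 + A3*Ts^3,
#            Ts = ln((298.15 - t)/(273.15 + t)), C in umol kg^-1 at
#            equilibrium with water-saturated air at 1 atm.
#   O2     : Garcia & Gordon (1992) Limnol. Oceanogr. 37, 1307-1312,
#            Benson & Krause refit; same functional form, degree 5.
#   N2O    : Weiss & Price (1980) Mar. Chem. 8, 347-359.
#            ln F = a1 + a2*(100/T) + a3*ln(T/100) + a4*(T/100)^2,
#            F in mol L^-1 atm^-1 for water-saturated air at 1 atm total
#            pressure; T in kelvin.
#   Water vapour pressure (atm): Weiss & Price (1980),
#            ln p = 24.4543 - 67.4509*(100/T) - 4.8489*ln(T/100).
#   Water density (kg/L): Kell (1975) polynomial.
#
# Thermodynamic formation values (kJ/mol, 298.15 K): CODATA key values for
# H2O(l), NO3-(aq); NBS/Thauer-style aqueous values for NH3(aq), dissolved
# gases derived from the gas-phase values plus Henry's-law transfer energies.

atmosphere:
  # dry-air mole fractions; n2o is the ambient tropospheric default and
  # n2o_calibration the NOAA standard used for GC calibration
  n2: 0.7808
  ar: 0.00934
  o2: 0.2095
  n2o: 332.0e-9
  n2o_calibration: 359.73e-9
  pressure_atm: 1.0

solubility:
  N2:
    form: hamme_emerson
    coefficients: [6.42931, 2.92704, 4.32531, 4.69149]
  Ar:
    form: hamme_emerson
    coefficients: [2.79150, 3.17609, 4.13116, 4.90379]
  O2:
    form: hamme_emerson
    coefficients: [5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369]
  N2O:
    form: weiss_price
    coefficients: [-165.8806, 222.8743, 92.0792, -1.48425]

vapour_pressure: [24.4543, -67.4509, -4.8489]

gas_constant_L_atm: 0.082057366
gas_constant_kJ: 8.314462618e-3

# Formation free energies / enthalpies at 298.15 K, kJ/mol.
# Aqueous dissolved-gas values = gas-phase formation value + RT ln(1/KH) with
# KH the Henry solubility (mol L^-1 atm^-1) and the van't Hoff enthalpy of
# dissolution folded into dHf.
thermo_species:
  H2O(l):   {dGf: -237.14, dHf: -285.83}
  NH3(aq):  {dGf: -26.57,  dHf: -80.29}
  O2(aq):   {dGf: 16.54,   dHf: -11.70}
  N2(aq):   {dGf: 18.23,   dHf: -10.50}
  N2O(aq):  {dGf: 113.32,  dHf: 62.10}
  NO3-(aq): {dGf: -111.25, dHf: -207.36}
  H+(aq):   {dGf: 0.0,     dHf: 0.0}
  e-:       {dGf: 0.0,     dHf: 0.0}

# Elemental composition (and charge) for stoichiometric balance checks.
thermo_elements:
  H2O(l):   {H: 2, O: 1, charge: 0}
  NH3(aq):  {N: 1, H: 3, charge: 0}
  O2(aq):   {O: 2, charge: 0}
  N2(aq):   {N: 2, charge: 0}
  N2O(aq):  {N: 2, O: 1, charge: 0}
  NO3-(aq): {N: 1, O: 3, charge: -1}
  H+(aq):   {H: 1, charge: 1}
  e-:       {charge: -1}

# The three N-acquisition reactions, written per mol NH3 produced.
reactions:
  N2O-fix:
    stoichiometry: {N2O(aq): -0.5, H2O(l): -1.5, NH3(aq): 1.0, O2(aq): 1.0}
  N2-fix:
    stoichiometry: {N2(aq): -0.5, H2O(l): -1.5, NH3(aq): 1.0, O2(aq): 0.75}
  NO3-assim:
    stoichiometry: {NO3-(aq): -1.0, H+(aq): -3.0, e-: -2.0, NH3(aq): 1.0, O2(aq): 1.5}

# Default activity set for the freshwater pond / incubation medium, mol/L
# (H+ as 10^-pH). NH3 at the colorimetric detection limit, O2 at 10 C air
# saturation, N2 at the ambient pool, N2O at the tracer addition level,
# NO3- at ambient sub-micromolar levels.
freshwater_medium:
  temperature_C: 10.0
  activities:
    NH3(aq): 2.0e-7
    O2(aq): 3.528e-4
    N2(aq): 4.87e-4
    N2O(aq): 9.0e-6
    NO3-(aq): 5.0e-7
    H+(aq): 1.0e-7
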