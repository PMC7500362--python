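# Default gas registry for mimsflux.
#
# `fragments` are electron-impact fragmentation patterns at unit m/z
# resolution, in percent of the base peak (base peak = 100).  Patterns
# depend on the ion source and its settings; replace this file with an
# instrument-specific table for quantitative work.
#
# `solubility` is [[temperature_C, C_eq], ...] with C_eq the equilibrium
# dissolved concentration (umol/L) in fresh water under 1 atm of the pure
# gas.  These are standard Henry-law reference values, NOT instrument
# calibration data; substitute medium-specific values (salinity!) as needed.
#
# `air_partial_pressure_atm` is the dry-air mole fraction used by the
# two-point (air/zero) calibration.  Gases absent from air carry 0 and
# need a spiked standard instead.
#
# Isotopologues (18O2, 16O18O, HD, 13CO2, 13C18O16O, 13C18O2) carry a
# single molecular-ion line and inherit the parent's solubility.

species:
  H2:
    formula: H2
    nominal_mz: 2
    fragments: {1: 2.0, 2: 100.0}
    air_partial_pressure_atm: 5.5e-7
    solubility:
      [[0, 960], [5, 910], [10, 870], [15, 840], [20, 810],
       [25, 786], [30, 767], [35, 752], [40, 740]]
  D2:
    formula: D2
    nominal_mz: 4
    fragments: {2: 1.59, 4: 100.0}
    air_partial_pressure_atm: 0.0
    solubility:
      [[0, 960], [5, 910], [10, 870], [15, 840], [20, 810],
       [25, 786], [30, 767], [35, 752], [40, 740]]
  H2O:
    formula: H2O
    nominal_mz: 18
    fragments: {16: 0.9, 17: 21.22, 18: 100.0, 19: 0.5}
    air_partial_pressure_atm: 0.0
    solubility: null
  N2:
    formula: N2
    nominal_mz: 28
    fragments: {14: 13.79, 28: 100.0, 29: 0.74}
    air_partial_pressure_atm: 0.7808
    solubility:
      [[0, 1047], [5, 925], [10, 826], [15, 747], [20, 684],
       [25, 629], [30, 582], [35, 544], [40, 511]]
  "NO":  # quoted: bare NO is a YAML 1.1 boolean
    formula: "NO"
    nominal_mz: 30
    fragments: {14: 7.51, 15: 2.4, 16: 1.5, 30: 100.0, 31: 0.4, 32: 0.2}
    air_partial_pressure_atm: 0.0
    solubility:
      [[0, 3270], [5, 2830], [10, 2480], [15, 2220], [20, 2010],
       [25, 1840], [30, 1700], [35, 1610], [40, 1510]]
  O2:
    formula: O2
    nominal_mz: 32
    fragments: {16: 21.8, 32: 100.0}
    air_partial_pressure_atm: 0.2095
    solubility:
      [[0, 2181], [5, 1913], [10, 1697], [15, 1527], [20, 1387],
       [25, 1263], [30, 1161], [35, 1074], [40, 1000]]
  Ar:
    formula: Ar
    nominal_mz: 40
    fragments: {20: 14.62, 36: 0.3, 38: 0.05, 40: 100.0}
    air_partial_pressure_atm: 0.00934
    solubility:
      [[0, 2420], [5, 2130], [10, 1890], [15, 1700], [20, 1550],
       [25, 1415], [30, 1300], [35, 1205], [40, 1125]]
  CO2:
    formula: CO2
    nominal_mz: 44
    fragments: {12: 8.71, 16: 9.61, 22: 1.9, 28: 9.81, 29: 0.1,
                44: 100.0, 45: 1.2, 46: 0.4}
    air_partial_pressure_atm: 4.15e-4
    solubility:
      [[0, 77000], [5, 63500], [10, 53000], [15, 45000], [20, 39000],
       [25, 33900], [30, 29900], [35, 26500], [40, 23600]]
  N2O:
    formula: N2O
    nominal_mz: 44
    fragments: {14: 12.91, 15: 0.1, 16: 5.0, 28: 10.81, 29: 0.1,
                30: 31.1, 44: 100.0, 45: 0.07}
    air_partial_pressure_atm: 3.3e-7
    solubility:
      [[0, 59300], [5, 48800], [10, 40700], [15, 34600], [20, 29800],
       [25, 25900], [30, 22800], [35, 20300], [40, 18300]]

  # --- isotopologues (molecular ion only) ---
  18O2:
    formula: "[18O]2"
    nominal_mz: 36
    fragments: {36: 100.0}
    isotopologue_of: O2
  16O18O:
    formula: "[16O][18O]"
    nominal_mz: 34
    fragments: {34: 100.0}
    isotopologue_of: O2
  HD:
    formula: HD
    nominal_mz: 3
    fragments: {3: 100.0}
    isotopologue_of: H2
  13CO2:
    formula: "[13C]O2"
    nominal_mz: 45
    fragments: {45: 100.0}
    isotopologue_of: CO2
  13C18O16O:
    formula: "[13C][18O][16O]"
    nominal_mz: 47
    fragments: {47: 100.0}
    isotopologue_of: CO2
  13C18O2:
    formula: "[13C][18O]2"
    nominal_mz: 49
    fragments: {49: 100.0}
    isotopologue_of: CO2
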