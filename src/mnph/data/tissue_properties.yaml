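# Default per-tissue physical properties for the multilayer torso model.
#
# Thermal values (density, specific heat, thermal conductivity, perfusion,
# metabolic heat) and low-frequency electrical conductivities are
# representative values transcribed from the IT'IS Foundation tissue-property
# database (thermal tables; dielectric values near 150 kHz).  They are
# documented defaults, not measurements performed by this package, and every
# entry can be overridden from a user config.
#
# Units:
#   density                  kg/m^3
#   specific_heat            J/(kg K)
#   conductivity             W/(m K)
#   perfusion                1/s   (blood volume per tissue volume per second;
#                                   IT'IS ml/min/kg converted via
#                                   w[1/s] = w[ml/min/kg] * rho / 6.0e7)
#   metabolic_rate           W/m^3 (IT'IS W/kg times density)
#   electrical_conductivity  S/m
blood:
  density: 1050.0
  specific_heat: 3617.0
  arterial_temperature: 37.0
tissues:
  skin:
    density: 1109.0
    specific_heat: 3391.0
    conductivity: 0.37
    perfusion: 1.96e-3        # 106 ml/min/kg
    metabolic_rate: 1830.0    # 1.65 W/kg
    electrical_conductivity: 1.2e-3
  fat:
    density: 911.0
    specific_heat: 2348.0
    conductivity: 0.21
    perfusion: 5.0e-4         # 33 ml/min/kg
    metabolic_rate: 465.0     # 0.51 W/kg
    electrical_conductivity: 0.024
  muscle:
    density: 1090.0
    specific_heat: 3421.0
    conductivity: 0.49
    perfusion: 6.7e-4         # 37 ml/min/kg
    metabolic_rate: 990.0     # 0.91 W/kg
    electrical_conductivity: 0.36
  pancreas:
    density: 1087.0
    specific_heat: 3164.0
    conductivity: 0.51
    perfusion: 1.39e-2        # 768 ml/min/kg
    metabolic_rate: 9180.0    # 8.44 W/kg
    electrical_conductivity: 0.52
# Pancreatic tumor properties equal the normal-pancreas values except for
# blood perfusion and metabolic rate, expressed as tumor:pancreas ratios.
# The ratio defaults below are package choices for a hypovascular pancreatic
# adenocarcinoma (NOT database values); both are overridable.
tumor:
  perfusion_ratio: 0.2
  metabolic_ratio: 1.0
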