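# Physical-property schema for the solvent table.
#
# One entry per numeric property column, in canonical column order.
# `unit` is documentation; `bounds` are physical-plausibility bounds used to
# clip synthetic data (they are NOT validation bounds for user data);
# `weight` is the default clustering/MDS weight for the column.
properties:
  - {name: Boiling_point,             unit: "degC",            bounds: [-50, 500],   weight: 1.0}
  - {name: Melting_point,             unit: "degC",            bounds: [-200, 300],  weight: 1.0}
  - {name: Vapor_pressure,            unit: "mmHg at 25 degC", bounds: [0, 5000],    weight: 1.0}
  - {name: Flash_point,               unit: "degC",            bounds: [-110, 400],  weight: 1.0}
  - {name: Autoignition_temperature,  unit: "degC",            bounds: [90, 700],    weight: 1.0}
  - {name: Hansen_delta_D,            unit: "MPa^0.5",         bounds: [10, 25],     weight: 1.0}
  - {name: Hansen_delta_P,            unit: "MPa^0.5",         bounds: [0, 30],      weight: 1.0}
  - {name: Hansen_delta_H,            unit: "MPa^0.5",         bounds: [0, 45],      weight: 1.0}
  - {name: Solubility_in_water,       unit: "g/L at 20 degC",  bounds: [0, 1000],    weight: 1.0}
  - {name: Density,                   unit: "kg/L at 25 degC", bounds: [0.4, 3.0],   weight: 1.0}
  - {name: Viscosity,                 unit: "mPa.s at 25 degC", bounds: [0.1, 1000], weight: 1.0}
  - {name: Relative_vapor_density,    unit: "air = 1",         bounds: [0.5, 20],    weight: 1.0}
  - {name: Log_P_octanol_water,       unit: "log10, 20 degC",  bounds: [-5, 10],     weight: 1.0}
  - {name: Refractive_index,          unit: "at 20 degC",      bounds: [1.2, 1.8],   weight: 1.0}
  - {name: Surface_tension,           unit: "mN/m at 25 degC", bounds: [10, 80],     weight: 1.0}
  - {name: Molar_volume,              unit: "mL/mol",          bounds: [30, 600],    weight: 1.0}
  - {name: Relative_evaporation_rate, unit: "BuAc = 100",      bounds: [0, 3000],    weight: 1.0}
  - {name: Antoine_A,                 unit: "-",               bounds: [3, 10],      weight: 1.0}
  - {name: Antoine_B,                 unit: "-",               bounds: [500, 5000],  weight: 1.0}
  - {name: Antoine_C,                 unit: "-",               bounds: [-150, 350],  weight: 1.0}
  - {name: Molecular_weight,          unit: "g/mol",           bounds: [16, 800],    weight: 1.0}
  - {name: Log_S,                     unit: "log10, 20 degC",  bounds: [-10, 2],     weight: 1.0}
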