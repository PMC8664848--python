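name,unit,lower,upper,hard_lower,hard_upper
pH,-,6,9,0,14
Alkalinity,mg-eq/L,0.5,6.5,0,
Hardness,mg-eq/L,,7,0,
Mineralization,mg-eq/L,,1000,0,
Ca,mg/L,,,0,
Mg,mg/L,,50,0,
Na,mg/L,,200,0,
K,mg/L,,,0,
NH4,mg/L,,2,0,
HCO3,mg/L,,,0,
Cl,mg/L,,350,0,
NO3,mg/L,,45,0,
NO2,mg/L,,3,0,
PO4,mg/L,,3.5,0,
SO4,mg/L,,500,0,
Cr,mg/L,,0.05,0,
Cu,mg/L,,1,0,
Fe,mg/L,,0.3,0,
Mn,mg/L,,0.1,0,
Ni,mg/L,,0.1,0,
Zn,mg/L,,5,0,
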