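# Default wheat FvCB kinetic constants (25 degC references).
gm_ref: 5.5          # mesophyll conductance, umol m-2 s-1 Pa-1
Ea_gm: 47.65         # kJ mol-1
Kair_ref: 772        # apparent carboxylation constant in 21% O2, umol mol-1
Ea_Kair: 93.72       # kJ mol-1
gammastar_ref: 37.74 # photorespiratory CO2 compensation point, umol mol-1
Ea_gammastar: 24.42  # kJ mol-1
pressure: 96         # kPa
T_ref: 298.15        # K
R: 8.314             # J mol-1 K-1
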