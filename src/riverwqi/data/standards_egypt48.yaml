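# Default standards/weights registry for Nile surface water.
#
# Statutory limits follow Egyptian Law 48/1982 for the protection of the
# Nile from pollution; parameters marked statutory: false have no limit
# in that law and carry documented placeholder guidelines (common aquatic
# -life screening values) — they are excluded from the indices by default.
#
# Ideal values: 0 for all ceiling parameters, 7.0 for pH, 14.6 mg/L for
# DO (oxygen saturation at 0 degC), following conventional weighted
# arithmetic WQI practice.  Weights rank parameters by human-health and
# ecological risk: 4 for the organic/toxic load (COD, BOD, TN, phenol,
# NH3-N), 3 for oxygen and nutrient status (DO, NO3-N, TP, turbidity,
# TSS), 2 for the major-ion group (TDS, pH, fluoride, sulfate, chloride),
# 1 for buffering/background (alkalinity, hardness, temperature,
# conductivity).  All of this is configuration, not ground truth: edit a
# copy of this file and pass it with --standards.
parameters:
  COD:        {unit: mg/L,   objective: ceiling, limit: 10,    weight: 4}
  BOD:        {unit: mg/L,   objective: ceiling, limit: 10,    weight: 4}
  TN:         {unit: ug/L,   objective: ceiling, limit: 3500,  weight: 4}
  phenol:     {unit: ug/L,   objective: ceiling, limit: 1,     weight: 4}
  NH3-N:      {unit: ug/L,   objective: ceiling, limit: 500,   weight: 4}
  DO:         {unit: mg/L,   objective: floor,   limit: 6,     ideal: 14.6, weight: 3}
  TP:         {unit: ug/L,   objective: ceiling, limit: 2000,  weight: 3}
  TDS:        {unit: mg/L,   objective: ceiling, limit: 500,   weight: 2}
  pH:         {unit: pH,     objective: range,   limit: [6.5, 8.5], ideal: 7.0, weight: 2}
  fluoride:   {unit: ug/L,   objective: ceiling, limit: 500,   weight: 2}
  sulfate:    {unit: mg/L,   objective: ceiling, limit: 200,   weight: 2}
  chloride:   {unit: mg/L,   objective: ceiling, limit: 250,   weight: 2}
  # --- no statutory limit in Law 48/1982: placeholder guidelines ---
  NO3-N:      {unit: ug/L,   objective: ceiling, limit: 2000,  weight: 3, statutory: false}
  turbidity:  {unit: NTU,    objective: ceiling, limit: 5,     weight: 3, statutory: false}
  TSS:        {unit: mg/L,   objective: ceiling, limit: 25,    weight: 3, statutory: false}
  alkalinity: {unit: mg/L,   objective: ceiling, limit: 200,   weight: 1, statutory: false}
  hardness:   {unit: mg/L,   objective: ceiling, limit: 500,   weight: 1, statutory: false}
  temperature: {unit: degC,  objective: ceiling, limit: 30,    weight: 1, statutory: false}
  conductivity: {unit: uS/cm, objective: ceiling, limit: 2000, weight: 1, statutory: false}
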