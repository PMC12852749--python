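# Unimpacted control scenario: no hotspots, every baseline comfortably
# inside its statutory limit in both seasons (dissolved oxygen included,
# unlike the impacted preset where summer DO dips below the floor).
name: clean_river
replicates: 3
seed: 0
layout:
  corridor_km: 120
  origin: {lon: 32.90, lat: 23.97}
  lateral_offset_m: 250
  sites:
    - {site_id: S1, along_km: 0,     sectors: [main, east, west]}
    - {site_id: S2, along_km: 58,    sectors: [main, east, west]}
    - {site_id: S3, along_km: 60,    sectors: [east]}
    - {site_id: S4, along_km: 63,    sectors: [main, east, west]}
    - {site_id: S5, along_km: 98,    sectors: [main, east, west]}
    - {site_id: S6, along_km: 100,   sectors: [east]}
    - {site_id: S7, along_km: 102,   sectors: [west]}
    - {site_id: S8, along_km: 103.5, sectors: [main, east, west]}
baselines:
  temperature:  {summer: 24.5,  winter: 17.5}
  pH:           {summer: 7.6,   winter: 7.6}
  DO:           {summer: 7.5,   winter: 8.5}
  TDS:          {summer: 190,   winter: 210}
  conductivity: {summer: 300,   winter: 330}
  COD:          {summer: 5.5,   winter: 6.0}
  BOD:          {summer: 3.3,   winter: 3.6}
  TN:           {summer: 650,   winter: 500}
  NO3-N:        {summer: 250,   winter: 200}
  NH3-N:        {summer: 85,    winter: 85}
  TP:           {summer: 40,    winter: 40}
  sulfate:      {summer: 20,    winter: 20}
  chloride:     {summer: 15,    winter: 15}
  fluoride:     {summer: 270,   winter: 270}
  alkalinity:   {summer: 117,   winter: 117}
  hardness:     {summer: 101,   winter: 101}
  TSS:          {summer: 2.0,   winter: 2.0}
  turbidity:    {summer: 0.55,  winter: 0.55}
  phenol:       {summer: 0.05,  winter: 0.05}
noise_cv:
  COD: 0.03
  BOD: 0.03
  TDS: 0.04
  conductivity: 0.04
  DO: 0.05
  TN: 0.08
  NO3-N: 0.08
  NH3-N: 0.10
  TP: 0.08
  sulfate: 0.08
  chloride: 0.08
  fluoride: 0.06
  alkalinity: 0.03
  hardness: 0.03
  TSS: 0.10
  turbidity: 0.12
  phenol: 0.10
additive_noise_sd:
  pH: 0.08
  temperature: 0.3
couplings:
  bod_from_cod_ratio: [0.5, 0.7]
  do_decrement_per_cod: 0.03
hotspots: []
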