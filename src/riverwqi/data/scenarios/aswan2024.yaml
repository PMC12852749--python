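# Synthetic stand-in for the 2024 Aswan-reach monitoring campaign.
#
# The layout copies the study design structurally (8 sites, 18 points,
# sector pattern 3-3-1-3-3-1-1-3 on a 120 km corridor); the geometry is
# synthetic.  Baselines and hotspot amplitudes are calibrated once to
# the campaign's reported background and near-discharge ranges: winter
# near-discharge COD 51.1-59.6 mg/L, hotspot turbidity 6.01-17.10 NTU
# against <1 NTU background, summer DO 3.82-5.50 vs winter 6.03-10.31
# mg/L, phenol 8.01-10.1 ug/L at the paper mill only, winter thermal
# plumes >21 degC against a 17.2-17.9 degC background, BOD/COD ratio
# 0.50-0.70.  Sugar mills operate January-May, so their hotspots are
# winter-only; the paper mill runs year-round; the ferroalloy plant
# discharges only low-heat cooling water (temperature, nothing else).
name: aswan2024
replicates: 3
seed: 0
layout:
  corridor_km: 120
  origin: {lon: 32.90, lat: 23.97}
  lateral_offset_m: 250
  sites:
    - {site_id: S1, city: Aswan,    along_km: 0,     sectors: [main, east, west],
       description: "Reference reach, no industrial source"}
    - {site_id: S2, city: Kom Ombo, along_km: 58,    sectors: [main, east, west],
       description: "1 km upstream of the sugar-mill drain"}
    - {site_id: S3, city: Kom Ombo, along_km: 60,    sectors: [east],
       description: "In front of the sugar-mill drain"}
    - {site_id: S4, city: Kom Ombo, along_km: 63,    sectors: [main, east, west],
       description: "3 km downstream of the sugar-mill drain"}
    - {site_id: S5, city: Edfu,     along_km: 98,    sectors: [main, east, west],
       description: "North of the bridge, upstream of the plants"}
    - {site_id: S6, city: Edfu,     along_km: 100,   sectors: [east],
       description: "In front of the ferroalloy discharge"}
    - {site_id: S7, city: Edfu,     along_km: 102,   sectors: [west],
       description: "In front of the sugar and paper mill discharge"}
    - {site_id: S8, city: Edfu,     along_km: 103.5, sectors: [main, east, west],
       description: "1.5 km downstream of the sugar/paper discharge"}
baselines:  # parameter -> seasonal background mean (registry units)
  temperature:  {summer: 24.5,  winter: 17.5}
  pH:           {summer: 7.6,   winter: 7.6}
  DO:           {summer: 4.6,   winter: 8.2}
  TDS:          {summer: 190,   winter: 210}
  conductivity: {summer: 300,   winter: 330}
  COD:          {summer: 5.5,   winter: 6.0}
  BOD:          {summer: 3.3,   winter: 3.6}   # overridden by the ratio coupling
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
noise_cv:  # multiplicative log-normal, typical analytical precision
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
  do_decrement_per_cod: 0.03   # mg/L DO lost per mg/L COD above background
hotspots:
  - name: berba_sugar          # winter-operating sugar mill via the drain
    along_km: 60
    across_m: 250
    decay_m: 500
    seasons: [winter]
    affected: {COD: 46, TN: 1600, NO3-N: 500, TSS: 6, turbidity: 8, temperature: 3.5}
  - name: edfu_sugar           # winter-operating sugar mill, co-located with the paper mill
    along_km: 102
    across_m: -250
    decay_m: 500
    seasons: [winter]
    affected: {COD: 29.3, TN: 900, NO3-N: 300, TSS: 3.5, turbidity: 4.5, temperature: 2.0}
  - name: edfu_paper           # paper mill, year-round, sole phenol source
    along_km: 102
    across_m: -250
    decay_m: 500
    seasons: [summer, winter]
    affected: {COD: 20, phenol: 8.95, TN: 800, NO3-N: 300, TSS: 3.5, turbidity: 6.0,
               temperature: 2.0}
  - name: ferroalloy           # low-heat cooling water only: no chemical load
    along_km: 100
    across_m: 250
    decay_m: 400
    seasons: [summer, winter]
    affected: {temperature: 4.2}
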