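{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Aarau",
   "Basel",
   "Geneva",
   "Lugano",
   "Payerne",
   "Wald"
  ],
  "altitude_band": "<1000m",
  "kind": "non_alpine"
 },
 "intercept": -0.83,
 "terms": [
  {
   "name": "NO2_2010",
   "coef": 0.855,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_25",
   "coef": 0.201,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "HDRES_250",
   "coef": 2.66e-05,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.64,
  "r2": 0.65,
  "rmse": 6.3,
  "loocv_r2": 0.63,
  "loocv_rmse": 6.4,
  "morans_i": 0.0658,
  "morans_i_p": 0.2217,
  "area_p": 0.001
 },
 "ranges": {},
 "truncation_exempt": [
  "NO2_2010"
 ],
 "forced": [],
 "n_sites": 234,
 "flags": []
}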