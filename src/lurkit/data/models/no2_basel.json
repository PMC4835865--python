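{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Basel"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": -1.86,
 "terms": [
  {
   "name": "NO2_2010",
   "coef": 0.738,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "HEAVYTRAFLOAD_25",
   "coef": 0.0019,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "HEAVYTRAFLOAD_500",
   "coef": 1.36e-06,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "WATER_500",
   "coef": 3.29e-05,
   "p": null,
   "direction": "either"
  }
 ],
 "stats": {
  "adj_r2": 0.76,
  "r2": 0.78,
  "rmse": 3.3,
  "loocv_r2": 0.64,
  "loocv_rmse": 4.0,
  "morans_i": -0.154,
  "morans_i_p": 0.0913
 },
 "ranges": {},
 "truncation_exempt": [
  "NO2_2010"
 ],
 "forced": [],
 "n_sites": 40,
 "flags": []
}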