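{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Wald"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": -10.3,
 "terms": [
  {
   "name": "HEAVYINTINVDIST",
   "coef": 1.35,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "NO2_2010",
   "coef": 1.15,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "POP_100",
   "coef": 0.029,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.89,
  "r2": 0.89,
  "rmse": 3.5,
  "loocv_r2": 0.86,
  "loocv_rmse": 3.9,
  "morans_i": -0.00939,
  "morans_i_p": 0.8613
 },
 "ranges": {},
 "truncation_exempt": [
  "NO2_2010"
 ],
 "forced": [],
 "n_sites": 39,
 "flags": []
}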