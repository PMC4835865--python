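{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Lugano"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": 14.1,
 "terms": [
  {
   "name": "TRAFMAJORLOAD_25",
   "coef": 2.93e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "TRAFMAJORLOAD_500",
   "coef": 3.31e-07,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "WATER_500",
   "coef": 4.36e-05,
   "p": null,
   "direction": "either"
  },
  {
   "name": "INTINVDIST",
   "coef": 0.00357,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "INDUSTRY_1000",
   "coef": 1.67e-05,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.64,
  "r2": 0.69,
  "rmse": 5.7,
  "loocv_r2": 0.57,
  "loocv_rmse": 6.3,
  "morans_i": -0.0804,
  "morans_i_p": 0.4878
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 37,
 "flags": []
}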