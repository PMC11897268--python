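{
 "vancomycin_1l2l": {
  "description": "vancomycin replaces linezolid in first- and second-line regimens; vial price inferred from the reference variant results (synthetic)",
  "replace_drug": "linezolid",
  "replacement": {
   "drug": "vancomycin",
   "dose_mg": 1000,
   "interval_h": 12,
   "duration_days": 12,
   "vial_price": 7.76,
   "price_inferred": true
  }
 },
 "cefiderocol_2l": {
  "description": "cefiderocol (plus linezolid) replaces both second-line options; vial price inferred from the reference variant results (synthetic)",
  "second_line": [
   [
    {
     "drug": "cefiderocol",
     "dose_mg": 2000,
     "interval_h": 8,
     "duration_days": 9.5,
     "vial_price": 262.17,
     "price_inferred": true
    },
    {
     "drug": "linezolid",
     "dose_mg": 600,
     "interval_h": 12,
     "duration_days": 12,
     "vial_price": 35.77
    }
   ]
  ]
 },
 "betalactam_stay": {
  "description": "lengths of stay observed with beta-lactam antibiotics; day values inferred by least squares from the reference variant results (synthetic)",
  "stay_cost_means": {
   "CE1L": 12654.16,
   "CECT": 16141.64,
   "CECST": 13052.9,
   "CEFST": 33421.86
  },
  "stay_days": {
   "stay_1L": 9.00808,
   "cure_with_TDM": 11.49071,
   "cure_without_TDM": 9.29193,
   "failure_without_TDM": 23.79194
  }
 }
}
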