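{
 "currency": "EUR (2024)",
 "deterministic": {
  "1": {
   "with_tdm": 16224,
   "without_tdm": 16000,
   "incremental": 224
  },
  "2": {
   "with_tdm": 15710,
   "without_tdm": 15966,
   "incremental": -256
  },
  "3": {
   "with_tdm": 15639,
   "without_tdm": 16341,
   "incremental": -702
  }
 },
 "psa": {
  "1": {
   "with_tdm": {
    "mean": 16120,
    "sd": 1405,
    "ci95": [
     16033,
     16207
    ]
   },
   "without_tdm": {
    "mean": 15925,
    "sd": 1385,
    "ci95": [
     15839,
     16010
    ]
   },
   "incremental": {
    "mean": 195,
    "se": 20
   },
   "p_saving_with_tdm": 39.4,
   "p_saving_without_tdm": 60.6
  },
  "2": {
   "with_tdm": {
    "mean": 15687,
    "sd": 1444,
    "ci95": [
     15597,
     15776
    ]
   },
   "without_tdm": {
    "mean": 15988,
    "sd": 1411,
    "ci95": [
     15901,
     16076
    ]
   },
   "incremental": {
    "mean": -301,
    "se": 33,
    "ci95_printed": [
     -300,
     -304
    ],
    "ci95_printed_inverted": true
   },
   "p_saving_with_tdm": 63.5,
   "p_saving_without_tdm": 36.5
  },
  "3": {
   "with_tdm": {
    "mean": 15623,
    "sd": 1407,
    "ci95": [
     15536,
     15710
    ]
   },
   "without_tdm": {
    "mean": 16308,
    "sd": 1393,
    "ci95": [
     16221,
     16394
    ]
   },
   "incremental": {
    "mean": -685,
    "se": 14
   },
   "p_saving_with_tdm": 79.7,
   "p_saving_without_tdm": 20.3
  }
 },
 "variants": {
  "1": {
   "vancomycin_1l2l": {
    "with_tdm": 15843,
    "without_tdm": 15590,
    "incremental": 253
   },
   "cefiderocol_2l": {
    "with_tdm": 18670,
    "without_tdm": 18643,
    "incremental": 27,
    "arm_costs_inconsistent_with_incremental": true
   },
   "betalactam_stay": {
    "with_tdm": 16461,
    "without_tdm": 16111,
    "incremental": 350
   }
  },
  "2": {
   "vancomycin_1l2l": {
    "with_tdm": 15331,
    "without_tdm": 15545,
    "incremental": -214
   },
   "cefiderocol_2l": {
    "with_tdm": 18144,
    "without_tdm": 18689,
    "incremental": -545,
    "arm_costs_inconsistent_with_incremental": true
   },
   "betalactam_stay": {
    "with_tdm": 15933,
    "without_tdm": 16122,
    "incremental": -189
   }
  },
  "3": {
   "vancomycin_1l2l": {
    "with_tdm": 15303,
    "without_tdm": 16005,
    "incremental": -702,
    "inconsistent_with_other_analyses": true
   },
   "cefiderocol_2l": {
    "with_tdm": 15974,
    "without_tdm": 17010,
    "incremental": -1036
   },
   "betalactam_stay": {
    "with_tdm": 15870,
    "without_tdm": 16536,
    "incremental": -666
   }
  }
 },
 "cure_rate_difference": {
  "1": 12.2,
  "2": 16.6,
  "3": 16.0
 },
 "tornado_analysis1": {
  "CECT": [
   -865,
   1315
  ],
  "CECST": [
   -533,
   982
  ],
  "ICCTDM": [
   -453,
   902
  ],
  "ICSTDM": [
   -402,
   851
  ],
  "IMSTDM": [
   -155,
   604
  ],
  "IMCTDM": [
   -91,
   540
  ],
  "CEFST": [
   -48,
   497
  ],
  "CTDM": [
   183,
   242
  ]
 },
 "regimen_costs": {
  "meropenem": 3182.22,
  "linezolid": 858.48,
  "ceftazidime-avibactam": 3277.5,
  "ceftolozane-tazobactam": 2475.09
 }
}
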