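{
 "schema_version": "1.0",
 "analysis_id": 2,
 "variant": "base",
 "source": "meta-analysis 2 (beta-lactams and vancomycin; RCTs)",
 "background_mortality": 0.0035,
 "arms": {
  "with_tdm": {
   "transitions": [
    {
     "code": "ICCTDM",
     "from_state": "treatment_1L",
     "to_state": "cure",
     "mean": 0.637,
     "low": 0.5733,
     "high": 0.7007,
     "sd": 0.0325,
     "printed_reversed": false
    },
    {
     "code": "IMCTDM",
     "from_state": "treatment_1L",
     "to_state": "death",
     "mean": 0.236,
     "low": 0.2124,
     "high": 0.2596,
     "sd": 0.012,
     "printed_reversed": false
    },
    {
     "code": "IFCTDM",
     "from_state": "treatment_1L",
     "to_state": "failure_2L",
     "mean": 0.127,
     "low": 0.0397,
     "high": 0.2143,
     "sd": 0.0445,
     "printed_reversed": true
    },
    {
     "code": "CMCTDM",
     "from_state": "cure",
     "to_state": "death",
     "mean": 0.0035,
     "low": 0.0032,
     "high": 0.0039,
     "sd": 0.0002,
     "printed_reversed": false
    },
    {
     "code": "CSCTDM",
     "from_state": "cure",
     "to_state": "discharge",
     "mean": 0.9965,
     "low": 0.9962,
     "high": 0.9969,
     "sd": 0.0002,
     "printed_reversed": true
    },
    {
     "code": "FCCTDM",
     "from_state": "failure_2L",
     "to_state": "cure",
     "mean": 0.7859,
     "low": 0.7073,
     "high": 0.8645,
     "sd": 0.0401,
     "printed_reversed": false
    },
    {
     "code": "FMCTDM",
     "from_state": "failure_2L",
     "to_state": "death",
     "mean": 0.2141,
     "low": 0.1355,
     "high": 0.2927,
     "sd": 0.0401,
     "printed_reversed": true
    }
   ]
  },
  "without_tdm": {
   "transitions": [
    {
     "code": "ICSTDM",
     "from_state": "treatment_1L",
     "to_state": "cure",
     "mean": 0.471,
     "low": 0.4239,
     "high": 0.5181,
     "sd": 0.024,
     "printed_reversed": false
    },
    {
     "code": "IMSTDM",
     "from_state": "treatment_1L",
     "to_state": "death",
     "mean": 0.276,
     "low": 0.2484,
     "high": 0.3036,
     "sd": 0.0141,
     "printed_reversed": false
    },
    {
     "code": "IFSTDM",
     "from_state": "treatment_1L",
     "to_state": "failure_2L",
     "mean": 0.253,
     "low": 0.1783,
     "high": 0.3277,
     "sd": 0.0381,
     "printed_reversed": true
    },
    {
     "code": "CMSTDM",
     "from_state": "cure",
     "to_state": "death",
     "mean": 0.0035,
     "low": 0.0032,
     "high": 0.0039,
     "sd": 0.0002,
     "printed_reversed": false
    },
    {
     "code": "CSSTDM",
     "from_state": "cure",
     "to_state": "discharge",
     "mean": 0.9965,
     "low": 0.9962,
     "high": 0.9969,
     "sd": 0.0002,
     "printed_reversed": true
    },
    {
     "code": "FCSTDM",
     "from_state": "failure_2L",
     "to_state": "cure",
     "mean": 0.7859,
     "low": 0.7073,
     "high": 0.8645,
     "sd": 0.0401,
     "printed_reversed": false
    },
    {
     "code": "FMSTDM",
     "from_state": "failure_2L",
     "to_state": "death",
     "mean": 0.2141,
     "low": 0.1355,
     "high": 0.2927,
     "sd": 0.0401,
     "printed_reversed": true
    }
   ]
  }
 },
 "costs": [
  {
   "code": "CE1L",
   "description": "ICU stay cost, first-line treatment",
   "mean": 12642.8,
   "low": 9833.29,
   "high": 19666.57,
   "sd": 2508.49,
   "sd_inferred": false
  },
  {
   "code": "CECT",
   "description": "ICU stay cost if cured, with TDM",
   "mean": 15803.49,
   "low": 12642.8,
   "high": 18964.19,
   "sd": 1612.6,
   "sd_inferred": false
  },
  {
   "code": "CECST",
   "description": "ICU stay cost if cured, without TDM",
   "mean": 13345.17,
   "low": 10676.14,
   "high": 16014.21,
   "sd": 1361.75,
   "sd_inferred": false
  },
  {
   "code": "CEFT",
   "description": "ICU stay cost if failure, with TDM",
   "mean": 31606.99,
   "low": 25285.59,
   "high": 37928.39,
   "sd": 3225.2,
   "sd_inferred": false
  },
  {
   "code": "CEFST",
   "description": "ICU stay cost if failure, without TDM",
   "mean": 31694.78,
   "low": 25355.83,
   "high": 38033.74,
   "sd": 3234.16,
   "sd_inferred": false
  },
  {
   "code": "CTDM",
   "description": "Unit cost of TDM (plasma level monitoring)",
   "mean": 170.66,
   "low": 87.84,
   "high": 204.79,
   "sd": 29.24,
   "sd_inferred": true
  },
  {
   "code": "CDUCI",
   "description": "Average daily cost in ICU",
   "mean": 1404.76,
   "low": 925.49,
   "high": 1110.58,
   "sd": 47.22,
   "sd_inferred": false
  },
  {
   "code": "CDHOSP",
   "description": "Average daily cost of hospitalization",
   "mean": 589.0,
   "low": 471.0,
   "high": 565.0,
   "sd": null,
   "sd_inferred": false
  }
 ],
 "regimens": {
  "first_line": [
   {
    "drug": "meropenem",
    "dose_mg": 1000,
    "interval_h": 8,
    "duration_days": 9,
    "vial_price": 117.86
   },
   {
    "drug": "linezolid",
    "dose_mg": 600,
    "interval_h": 12,
    "duration_days": 12,
    "vial_price": 35.77
   }
  ],
  "second_line": [
   [
    {
     "drug": "ceftazidime-avibactam",
     "dose_mg": 2000,
     "interval_h": 8,
     "duration_days": 9.5,
     "vial_price": 115.0
    },
    {
     "drug": "linezolid",
     "dose_mg": 600,
     "interval_h": 12,
     "duration_days": 12,
     "vial_price": 35.77
    }
   ],
   [
    {
     "drug": "ceftolozane-tazobactam",
     "dose_mg": 1000,
     "interval_h": 8,
     "duration_days": 9,
     "vial_price": 91.67
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
 "stays": [
  {
   "state_role": "stay_1L",
   "days_mean": 9.0,
   "days_low": 7.0,
   "days_high": 14.0,
   "days_display": 9.0,
   "unit_cost_per_day": 1404.7555555555555,
   "cost_code": "CE1L"
  },
  {
   "state_role": "cure_with_TDM",
   "days_mean": 11.25,
   "days_low": 9.0,
   "days_high": 13.5,
   "days_display": 11.3,
   "unit_cost_per_day": 1404.7555555555555,
   "cost_code": "CECT"
  },
  {
   "state_role": "cure_without_TDM",
   "days_mean": 9.5,
   "days_low": 7.6,
   "days_high": 11.4,
   "days_display": 9.5,
   "unit_cost_per_day": 1404.7555555555555,
   "cost_code": "CECST"
  },
  {
   "state_role": "failure_with_TDM",
   "days_mean": 22.5,
   "days_low": 18.0,
   "days_high": 27.0,
   "days_display": 22.5,
   "unit_cost_per_day": 1404.7555555555555,
   "cost_code": "CEFT"
  },
  {
   "state_role": "failure_without_TDM",
   "days_mean": 22.5625,
   "days_low": 18.05,
   "days_high": 27.075,
   "days_display": 22.6,
   "unit_cost_per_day": 1404.7555555555555,
   "cost_code": "CEFST"
  }
 ]
}
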