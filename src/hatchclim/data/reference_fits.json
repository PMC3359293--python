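{
  "hatching_success": {
    "response": "hatching_success",
    "predictor_names": ["precip_prev2_mm", "precip_oct_mm", "temp_incubation_c"],
    "intercept": 1.87,
    "coefficients": {
      "precip_prev2_mm": 1.83e-4,
      "precip_oct_mm": 3.23e-4,
      "temp_incubation_c": -6.06e-2
    },
    "standard_errors": {
      "intercept": 0.76,
      "precip_prev2_mm": 4.94e-5,
      "precip_oct_mm": 8.02e-5,
      "temp_incubation_c": 2.79e-2
    },
    "p_values": {
      "precip_prev2_mm": 0.002,
      "precip_oct_mm": 0.001,
      "temp_incubation_c": 0.05
    },
    "r_squared": 0.81,
    "n": 24,
    "standardized_coefficients": {
      "precip_prev2_mm": 0.46,
      "precip_oct_mm": 0.45,
      "temp_incubation_c": -0.24
    }
  },
  "emergence_rate": {
    "response": "emergence_rate",
    "predictor_names": ["temp_incubation_c", "precip_sep_oct_mm"],
    "intercept": 4.51,
    "coefficients": {
      "temp_incubation_c": -0.14,
      "precip_sep_oct_mm": 1.62e-4
    },
    "standard_errors": {
      "intercept": 0.81,
      "temp_incubation_c": 0.03,
      "precip_sep_oct_mm": 4.80e-5
    },
    "p_values": {
      "temp_incubation_c": 0.001,
      "precip_sep_oct_mm": 0.01
    },
    "r_squared": 0.65,
    "n": 24,
    "standardized_coefficients": {
      "temp_incubation_c": -0.62,
      "precip_sep_oct_mm": 0.44
    }
  }
}
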