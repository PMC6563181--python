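{
  "version": 1,
  "description": "Published discriminant functions for sternal measurements and indices (Croatian population reference). Scores above the sectioning point classify as male, below as female. Variables are in cm (SA in cm^2, SI dimensionless).",
  "orientation": "score_above_sectioning_point_is_male",
  "functions": [
    {
      "name": "mw_b_csw1",
      "variables": ["MW", "B", "CSW1"],
      "coefficients": [0.965, 0.712, 1.793],
      "constant": -17.123,
      "sectioning_point": -0.183,
      "published_rates": {"men": 89.0, "women": 92.7, "overall": 90.6}
    },
    {
      "name": "m",
      "variables": ["M"],
      "coefficients": [2.224],
      "constant": -11.653,
      "sectioning_point": 0.07,
      "published_rates": {"men": 64.4, "women": 72.7, "overall": 68.0}
    },
    {
      "name": "mw",
      "variables": ["MW"],
      "coefficients": [2.401],
      "constant": -13.642,
      "sectioning_point": -0.1195,
      "published_rates": {"men": 78.1, "women": 80.0, "overall": 78.9}
    },
    {
      "name": "b",
      "variables": ["B"],
      "coefficients": [1.008],
      "constant": -9.676,
      "sectioning_point": -0.1185,
      "published_rates": {"men": 83.6, "women": 81.8, "overall": 82.8}
    },
    {
      "name": "csw1",
      "variables": ["CSW1"],
      "coefficients": [3.209],
      "constant": -8.590,
      "sectioning_point": -0.0915,
      "published_rates": {"men": 72.6, "women": 74.5, "overall": 73.4}
    },
    {
      "name": "csw2",
      "variables": ["CSW2"],
      "coefficients": [1.920],
      "constant": -6.117,
      "sectioning_point": -0.072,
      "published_rates": {"men": 65.8, "women": 69.1, "overall": 67.2}
    },
    {
      "name": "cl",
      "variables": ["CL"],
      "coefficients": [0.934],
      "constant": -13.991,
      "sectioning_point": -0.1405,
      "published_rates": {"men": 84.9, "women": 83.6, "overall": 84.4}
    },
    {
      "name": "si",
      "variables": ["SI"],
      "coefficients": [0.125],
      "constant": -6.912,
      "sectioning_point": 0.046,
      "published_rates": {"men": 69.9, "women": 54.5, "overall": 63.3}
    },
    {
      "name": "sa",
      "variables": ["SA"],
      "coefficients": [0.069],
      "constant": -4.019,
      "sectioning_point": -0.088,
      "published_rates": {"men": 84.9, "women": 94.5, "overall": 89.1}
    }
  ]
}
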