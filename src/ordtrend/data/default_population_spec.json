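{
  "classes": [
    {"label": "underweight", "lower": 14.2, "upper": 18.5, "proportion": 0.017, "median": 17.8, "log_scale": 0.0661},
    {"label": "normal weight", "lower": 18.5, "upper": 25.0, "proportion": 0.273, "median": 22.7, "log_scale": 0.0753},
    {"label": "overweight", "lower": 25.0, "upper": 30.0, "proportion": 0.346, "median": 27.5, "log_scale": 0.0456},
    {"label": "obese", "lower": 30.0, "upper": 67.3, "proportion": 0.365, "median": 34.0, "log_scale": 0.30}
  ],
  "range_limits": [14.2, 67.3],
  "target_mean": 28.9,
  "target_sd": 6.6
}
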