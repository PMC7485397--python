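{
  "modality": "bmode",
  "selected_indices": [747, 637, 535, 719, 518, 565, 532],
  "coefficients": [-0.3351454, -0.5255682, -0.2029134, -0.8266571, -0.7043252, -0.7884457, -0.9791398],
  "intercept": 3.6044336,
  "threshold": -1.28,
  "lambda_": null,
  "orientation": "lower_is_malignant",
  "standardized": false,
  "feature_means": null,
  "feature_scales": null,
  "seed": null,
  "notes": "Frozen published reference B-mode rad-score formula over the 768-dim deep feature vector; orientation relative to the printed threshold is an assumption (all coefficients are negative). Used for scoring-arithmetic validation only."
}
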