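{
  "comment": "Synthetic craniofacial landmark template (mm) in the standardized frame: nasion at the origin, +x subject's left, +y anterior, +z superior. Hand-calibrated so the 21 derived measurements approximate the Japanese male cohort means; md is derived, not stored.",
  "landmarks": {
    "g":    [0.0, 2.34, 11.71],
    "n":    [0.0, 0.0, 0.0],
    "dR":   [-9.68, -7.51, -8.76],
    "dL":   [9.68, -7.51, -8.76],
    "sorR": [-29.77, 5.0, 8.0],
    "sorL": [29.77, 5.0, 8.0],
    "rhi":  [0.0, 13.22, -22.71],
    "orR":  [-30.22, 6.0, -14.0],
    "orL":  [30.22, 6.0, -14.0],
    "fzsR": [-52.42, -8.0, -6.0],
    "fzsL": [52.42, -8.0, -6.0],
    "ans":  [0.0, 18.5, -53.1],
    "pns":  [0.0, -32.0, -51.0],
    "poR":  [-62.3, -70.0, -14.0],
    "poL":  [62.3, -70.0, -14.0],
    "s":    [0.0, -65.0, -14.0],
    "A":    [0.0, 22.4, -57.0],
    "B":    [0.0, 14.0, -95.0],
    "ba":   [0.0, -66.0, -78.5],
    "me":   [0.0, 4.0, -125.97]
  },
  "calibration": {
    "landmark_noise_sd_mm": 0.7,
    "digitization_sd_mm": 0.3,
    "female_scale": 0.94,
    "female_nasion_anterior_mm": 0.45,
    "population_nasion_anterior_mm": {
      "Japanese": 0.0,
      "Korean": 0.0,
      "Egyptian": 1.0
    }
  }
}
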