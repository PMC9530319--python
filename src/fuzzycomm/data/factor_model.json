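{
  "description": "Published two-component factor model for the nine communication indicators: factor loadings, the corresponding principal-component score coefficients, and the normalized indicator weight vector.",
  "indicator_order": ["auditory", "visual", "memory", "comprehension", "judgment", "expression", "attention", "speech_energy", "speech_speed"],
  "loadings": [
    [0.979, 0.018],
    [0.947, 0.278],
    [0.936, 0.082],
    [0.975, -0.132],
    [0.889, -0.418],
    [0.959, -0.200],
    [0.996, 0.014],
    [0.233, 0.972],
    [0.770, 0.130]
  ],
  "score_coefficients": [
    [0.3703, 0.0151],
    [0.3547, 0.2457],
    [0.3502, 0.0718],
    [0.3684, -0.1162],
    [0.3358, -0.3699],
    [0.3627, -0.1765],
    [0.3767, 0.0115],
    [0.0878, 0.8604],
    [0.2911, 0.1144]
  ],
  "weights": [0.1237, 0.1324, 0.1204, 0.1151, 0.0890, 0.1096, 0.1255, 0.0810, 0.1034],
  "n_subjects": 50
}
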