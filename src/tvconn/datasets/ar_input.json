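{
  "description": "Fixed AR(10) process emulating a cortical visual-input signal: 1/f-like spectral decay with an alpha-band (8-12 Hz) resonance at a 256 Hz sampling rate. Coefficients a_k enter as x(n) = sum_k a_k x(n-k) + e(n). Constructed from complex pole pairs (frequency Hz, modulus) and real poles listed under 'poles'.",
  "fs_hz": 256.0,
  "order": 10,
  "poles": {
    "complex_pairs": [[10.0, 0.95], [20.0, 0.8], [35.0, 0.72], [55.0, 0.68]],
    "real": [0.96, 0.7]
  },
  "coefficients": [
    6.1526799844937825,
    -17.56450633268621,
    30.958278555410416,
    -37.719349808527156,
    33.53867992507549,
    -22.229453949608754,
    10.910994194134174,
    -3.808143942524763,
    0.8537535573888472,
    -0.093042051121152
  ]
}
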