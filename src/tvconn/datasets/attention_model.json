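{
  "description": "Default ground-truth visual spatial attention network: 10 cortical regions (MNI mm coordinates) and 23 directed connections. Interhemispheric couplings are stationary at 0.5; all other couplings have a 0.2 stationary baseline plus a raised-cosine time-varying bump (onset_ms relative to stimulus onset, i.e. the end of the baseline period). Lags are in milliseconds at fs = 256 Hz (16 ms = 4 samples, 4 ms = 1 sample).",
  "fs_hz": 256.0,
  "duration_ms": 1200.0,
  "baseline_ms": 200.0,
  "source_snr": 20.0,
  "regions": [
    {"label": "V1",    "name": "Primary visual cortex (V1)",                        "mni_xyz": [6.3, -82.3, -3.7], "hemisphere": "right"},
    {"label": "VA_R",  "name": "Right visual area (R VA)",                          "mni_xyz": [15.0, -71.0, 5.0], "hemisphere": "right"},
    {"label": "IPS_R", "name": "Right intraparietal sulcus (IPS R)",                "mni_xyz": [42.0, -42.0, 48.0], "hemisphere": "right"},
    {"label": "FEF_R", "name": "Right frontal eye fields (FEF R)",                  "mni_xyz": [38.0, -6.0, 56.0], "hemisphere": "right"},
    {"label": "TPJ_R", "name": "Right temporoparietal junction (TPJ R)",            "mni_xyz": [66.0, -48.0, 20.0], "hemisphere": "right"},
    {"label": "VFC_R", "name": "Right ventral frontal cortex/anterior insula (VFC/AI R)", "mni_xyz": [39.0, 0.0, 39.0], "hemisphere": "right"},
    {"label": "MFG_R", "name": "Right middle frontal gyrus (MFG R)",                "mni_xyz": [47.0, 38.0, 29.0], "hemisphere": "right"},
    {"label": "VA_L",  "name": "Left visual area (VA L)",                           "mni_xyz": [-14.0, -81.0, 9.0], "hemisphere": "left"},
    {"label": "IPS_L", "name": "Left intraparietal sulcus (IPS L)",                 "mni_xyz": [-44.0, -57.0, 48.0], "hemisphere": "left"},
    {"label": "FEF_L", "name": "Left frontal eye fields (FEF L)",                   "mni_xyz": [-43.0, -7.0, 52.0], "hemisphere": "left"}
  ],
  "tv_defaults": {"duration_ms": 200.0, "peak_amplitude": 0.15},
  "connections": [
    {"sender": "V1",    "receiver": "VA_L",  "lag_ms": 4,  "baseline_strength": 0.2, "category": "input",           "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "V1",    "receiver": "VA_R",  "lag_ms": 4,  "baseline_strength": 0.2, "category": "input",           "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},

    {"sender": "VA_L",  "receiver": "VA_R",  "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},
    {"sender": "VA_R",  "receiver": "VA_L",  "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},
    {"sender": "IPS_L", "receiver": "IPS_R", "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},
    {"sender": "IPS_R", "receiver": "IPS_L", "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},
    {"sender": "FEF_L", "receiver": "FEF_R", "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},
    {"sender": "FEF_R", "receiver": "FEF_L", "lag_ms": 16, "baseline_strength": 0.5, "category": "interhemispheric", "tv_waveform": null},

    {"sender": "IPS_L", "receiver": "VA_L",  "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "IPS_R", "receiver": "VA_R",  "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "FEF_L", "receiver": "IPS_L", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "FEF_R", "receiver": "IPS_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "IPS_L", "receiver": "FEF_L", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "IPS_R", "receiver": "FEF_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "MFG_R", "receiver": "FEF_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "MFG_R", "receiver": "TPJ_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "top_down",        "tv_waveform": {"onset_ms": 300.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},

    {"sender": "VA_R",  "receiver": "TPJ_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "VA_L",  "receiver": "TPJ_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "TPJ_R", "receiver": "VFC_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "VFC_R", "receiver": "TPJ_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "TPJ_R", "receiver": "IPS_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "FEF_R", "receiver": "MFG_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}},
    {"sender": "TPJ_R", "receiver": "MFG_R", "lag_ms": 16, "baseline_strength": 0.2, "category": "stimulus_driven", "tv_waveform": {"onset_ms": 100.0, "duration_ms": 200.0, "peak_amplitude": 0.15}}
  ]
}
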