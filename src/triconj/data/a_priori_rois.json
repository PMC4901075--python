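{
  "version": 1,
  "radius_mm": 5.0,
  "space": "MNI",
  "rois": [
    {"name": "L_striatum", "domain": "value", "center_mm": [-12, 12, -6]},
    {"name": "R_striatum", "domain": "value", "center_mm": [12, 10, -6]},
    {"name": "L_medial_frontal", "domain": "value", "center_mm": [-2, 40, -8]},
    {"name": "R_medial_frontal", "domain": "value", "center_mm": [2, 46, 8]},
    {"name": "L_lateral_frontal", "domain": "mathematical", "center_mm": [-42, 4, 40]},
    {"name": "R_lateral_frontal", "domain": "mathematical", "center_mm": [46, 10, 28]},
    {"name": "L_superior_parietal", "domain": "mathematical", "center_mm": [-26, -60, 46]},
    {"name": "R_superior_parietal", "domain": "mathematical", "center_mm": [30, -62, 44]},
    {"name": "L_inferior_parietal", "domain": "mathematical", "center_mm": [-44, -40, 42]},
    {"name": "R_inferior_parietal", "domain": "mathematical", "center_mm": [38, -46, 42]},
    {"name": "L_middle_temporal", "domain": "emotion", "center_mm": [-56, -58, 4]},
    {"name": "R_middle_temporal", "domain": "emotion", "center_mm": [56, -44, 4]},
    {"name": "L_insula", "domain": "emotion", "center_mm": [-26, 20, -4]},
    {"name": "R_insula", "domain": "emotion", "center_mm": [42, 10, 12]},
    {"name": "R_amygdala", "domain": "emotion", "center_mm": [25, -1, -17]},
    {"name": "L_anterior_cingulate", "domain": "emotion", "center_mm": [-6, 36, 22]}
  ]
}
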