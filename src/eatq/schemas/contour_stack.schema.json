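{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "eatq contour stack",
 "description": "Ordered planar tracings of cardiac structures on a short-axis slice stack. Coordinates in millimetres; slice_index 0 is the most basal slice.",
 "type": "object",
 "required": ["format_version", "subject_id", "slice_thickness_mm", "inter_slice_gap_mm", "n_slices", "contours"],
 "properties": {
  "format_version": {"const": "1.0"},
  "subject_id": {"type": "string"},
  "slice_thickness_mm": {"type": "number", "exclusiveMinimum": 0},
  "inter_slice_gap_mm": {"type": "number", "minimum": 0},
  "n_slices": {"type": "integer", "minimum": 1},
  "contours": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["slice_index", "phase", "structure", "points"],
    "properties": {
     "slice_index": {"type": "integer", "minimum": 0},
     "phase": {"enum": ["end_diastole", "end_systole"]},
     "structure": {"enum": ["lv_endo", "lv_epi", "rv_endo", "eat", "lge"]},
     "role": {"enum": ["outer", "hole"], "default": "outer"},
     "points": {
      "type": "array",
      "minItems": 3,
      "items": {"type": "array", "prefixItems": [{"type": "number"}, {"type": "number"}], "minItems": 2, "maxItems": 2}
     }
    }
   }
  }
 }
}
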