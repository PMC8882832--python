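{
 "name": "fujian_13",
 "cores": [
  {
   "core_id": 1,
   "side": "right",
   "level": "base",
   "laterality": "medial",
   "x": 0.25,
   "y": -0.5,
   "z": -0.7
  },
  {
   "core_id": 2,
   "side": "right",
   "level": "base",
   "laterality": "lateral",
   "x": 0.75,
   "y": -0.5,
   "z": -0.7
  },
  {
   "core_id": 3,
   "side": "left",
   "level": "base",
   "laterality": "medial",
   "x": -0.25,
   "y": -0.5,
   "z": -0.7
  },
  {
   "core_id": 4,
   "side": "left",
   "level": "base",
   "laterality": "lateral",
   "x": -0.75,
   "y": -0.5,
   "z": -0.7
  },
  {
   "core_id": 5,
   "side": "right",
   "level": "mid",
   "laterality": "medial",
   "x": 0.25,
   "y": -0.5,
   "z": 0.0
  },
  {
   "core_id": 6,
   "side": "right",
   "level": "mid",
   "laterality": "lateral",
   "x": 0.75,
   "y": -0.5,
   "z": 0.0
  },
  {
   "core_id": 7,
   "side": "left",
   "level": "mid",
   "laterality": "medial",
   "x": -0.25,
   "y": -0.5,
   "z": 0.0
  },
  {
   "core_id": 8,
   "side": "left",
   "level": "mid",
   "laterality": "lateral",
   "x": -0.75,
   "y": -0.5,
   "z": 0.0
  },
  {
   "core_id": 9,
   "side": "right",
   "level": "apex",
   "laterality": "medial",
   "x": 0.25,
   "y": -0.5,
   "z": 0.7
  },
  {
   "core_id": 10,
   "side": "right",
   "level": "apex",
   "laterality": "lateral",
   "x": 0.75,
   "y": -0.5,
   "z": 0.7
  },
  {
   "core_id": 11,
   "side": "left",
   "level": "apex",
   "laterality": "medial",
   "x": -0.25,
   "y": -0.5,
   "z": 0.7
  },
  {
   "core_id": 12,
   "side": "left",
   "level": "apex",
   "laterality": "lateral",
   "x": -0.75,
   "y": -0.5,
   "z": 0.7
  },
  {
   "core_id": 13,
   "side": "midline",
   "level": "mid",
   "laterality": "midline",
   "x": 0.0,
   "y": -0.5,
   "z": 0.0
  }
 ]
}
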