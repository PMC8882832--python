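{
 "sectors": [
  {
   "side": "right",
   "level": "base",
   "zone": "peripheral",
   "x": 0.5,
   "y": -0.5,
   "z": -0.7
  },
  {
   "side": "right",
   "level": "base",
   "zone": "transition",
   "x": 0.3,
   "y": 0.0,
   "z": -0.7
  },
  {
   "side": "right",
   "level": "mid",
   "zone": "peripheral",
   "x": 0.5,
   "y": -0.5,
   "z": 0.0
  },
  {
   "side": "right",
   "level": "mid",
   "zone": "transition",
   "x": 0.3,
   "y": 0.0,
   "z": 0.0
  },
  {
   "side": "right",
   "level": "apex",
   "zone": "peripheral",
   "x": 0.5,
   "y": -0.5,
   "z": 0.7
  },
  {
   "side": "right",
   "level": "apex",
   "zone": "transition",
   "x": 0.3,
   "y": 0.0,
   "z": 0.7
  },
  {
   "side": "left",
   "level": "base",
   "zone": "peripheral",
   "x": -0.5,
   "y": -0.5,
   "z": -0.7
  },
  {
   "side": "left",
   "level": "base",
   "zone": "transition",
   "x": -0.3,
   "y": 0.0,
   "z": -0.7
  },
  {
   "side": "left",
   "level": "mid",
   "zone": "peripheral",
   "x": -0.5,
   "y": -0.5,
   "z": 0.0
  },
  {
   "side": "left",
   "level": "mid",
   "zone": "transition",
   "x": -0.3,
   "y": 0.0,
   "z": 0.0
  },
  {
   "side": "left",
   "level": "apex",
   "zone": "peripheral",
   "x": -0.5,
   "y": -0.5,
   "z": 0.7
  },
  {
   "side": "left",
   "level": "apex",
   "zone": "transition",
   "x": -0.3,
   "y": 0.0,
   "z": 0.7
  }
 ]
}
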