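{
 "0": [
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ],
  [
   0.2368,
   0.5101,
   0.6291,
   0.5101,
   0.2368
  ],
  [
   0.2921,
   0.6291,
   0.7726,
   0.6291,
   0.2921
  ],
  [
   0.2368,
   0.5101,
   0.6291,
   0.5101,
   0.2368
  ],
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ]
 ],
 "45": [
  [
   0.0,
   0.0,
   0.1105,
   0.2368,
   0.1105
  ],
  [
   0.0,
   0.0,
   0.2368,
   0.5101,
   0.2368
  ],
  [
   0.1105,
   0.2368,
   0.5101,
   0.6291,
   0.2921
  ],
  [
   0.2368,
   0.5101,
   0.6291,
   0.5101,
   0.2368
  ],
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ]
 ],
 "90": [
  [
   -0.1105,
   -0.2368,
   0.0,
   0.2368,
   0.1105
  ],
  [
   -0.2368,
   -0.5101,
   0.0,
   0.5101,
   0.2368
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.2368,
   0.5101,
   0.0,
   0.5101,
   0.2368
  ],
  [
   0.1105,
   0.2368,
   0.0,
   0.2368,
   0.1105
  ]
 ],
 "135": [
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ],
  [
   0.2368,
   0.5101,
   0.6291,
   0.5101,
   0.2368
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   -0.2368,
   -0.5101,
   0.0,
   0.5101,
   0.2368
  ],
  [
   -0.1105,
   -0.2368,
   0.0,
   0.2368,
   0.1105
  ]
 ],
 "180": [
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ],
  [
   0.2368,
   0.5101,
   0.6291,
   0.5101,
   0.2368
  ],
  [
   0.1105,
   0.2368,
   0.2921,
   0.2368,
   0.1105
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   -0.1105,
   -0.2368,
   0.0,
   0.2368,
   0.1105
  ]
 ]
}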