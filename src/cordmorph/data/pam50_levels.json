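{
  "description": "Vertebral level boundaries of the PAM50 spinal cord template, expressed as axial slice indices (index increases toward superior; one slice every 0.5 mm). Key k is the disc at the top of vertebra k (k=2 is the C1-C2 disc); key 1 is the superior boundary of C1 and is not an anatomical disc. The level of vertebra k spans slices [boundary[k+1], boundary[k]-1].",
  "slice_thickness_mm": 0.5,
  "boundaries": {
    "1": 964,
    "2": 939,
    "3": 908,
    "4": 871,
    "5": 834,
    "6": 801,
    "7": 770,
    "8": 736,
    "9": 692
  }
}
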