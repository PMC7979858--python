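# PVM pipeline on a synthetic reference video (reduced 60x60 frame).
synthetic:
  height: 60
  width: 60
  n_frames: 1550
  seed: 1
sampling_areas: [1, 3, 6, 15, 30, 60]
seed: 1
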