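# Desk-scale synthetic recording: a 30 s take (900 frames) at 30 Hz.
# One lower-left limb strokes at 1.5 Hz; everything else is still.
frame_size: [240, 320]
body_axes: [150.0, 75.0]
n_frames: 900
limbs:
  - {region: LL, frequency: 1.5, amplitude: 20.0}
noise_sd: 2.0
seed: 1
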